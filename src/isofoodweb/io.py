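"""Readers, writers, run manifest and the end-to-end pipeline.

CSV dialect: comma-separated, UTF-8, mandatory header row, "." decimal
separator. Per-mil values are stored as plain floats. The pipeline writes a
run manifest (config snapshot, seeds, input digests) *before* any results,
then community, niche and mixing outputs, then a JSON run report with the
test statistics.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    CommunityTable,
    density_table,
    replicate_diversity,
    sorensen_index,
    trophic_group_composition,
    two_sample_t_test,
)
from .exceptions import ParseError
from .mixing import TEF, MixingModel, aggregate_sources
from .niche import (
    ellipse_overlap,
    select_baseline,
    summarize_niche,
    trophic_level_table,
)
from .synthetic import generate_study, paper_like_config

log = logging.getLogger("isofoodweb")
if not log.handlers:  # stage-prefixed logging to stderr; results go to files
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

ABUNDANCE_COLUMNS = ["site", "replicate", "taxon", "count", "trophic_group"]
ISOTOPE_COLUMNS = ["entity", "entity_class", "site", "d13C", "d15N"]


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def read_abundance_table(path, quadrat_area: float) -> list[CommunityTable]:
    """Read a long-format abundance CSV into CommunityTables.

    Columns: site, replicate, taxon, count, trophic_group. Rejects missing
    columns, negative or non-integer counts and duplicate
    (site, replicate, taxon) rows, naming the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ABUNDANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")

    bad = df.index[(pd.to_numeric(df["count"], errors="coerce").isna())
                   | (df["count"].astype(float) < 0)
                   | (df["count"].astype(float) % 1 != 0)]
    if len(bad):
        rows = [int(i) + 2 for i in bad]  # header is line 1
        raise ParseError(f"{path.name}: invalid counts at rows {rows}")

    dup = df.duplicated(subset=["site", "replicate", "taxon"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup]]
        raise ParseError(
            f"{path.name}: duplicate (site, replicate, taxon) rows {rows}"
        )

    tables = []
    for (site, rep), grp in df.groupby(["site", "replicate"], sort=True):
        counts = {str(r.taxon): int(r.count) for r in grp.itertuples()}
        trophic = {
            str(r.taxon): str(r.trophic_group)
            for r in grp.itertuples()
            if isinstance(r.trophic_group, str) and r.trophic_group
        }
        tables.append(
            CommunityTable(
                site=str(site),
                replicate=str(rep),
                quadrat_area=quadrat_area,
                counts=counts,
                trophic_group=trophic,
            )
        )
    return tables


def write_abundance_table(tables: Iterable[CommunityTable], path) -> None:
    rows = []
    for t in tables:
        for taxon in sorted(t.counts):
            rows.append(
                {
                    "site": t.site,
                    "replicate": t.replicate,
                    "taxon": taxon,
                    "count": t.counts[taxon],
                    "trophic_group": t.group_of(taxon),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_isotope_table(path) -> pd.DataFrame:
    """Read a specimen-level isotope CSV.

    Columns: entity, entity_class (source|consumer), site, d13C, d15N, plus
    optional specimen/source_group/trophic_group columns. Implausible |delta|
    values (> 100 permil) trigger a warning via the niche module when used.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")
    bad_class = ~df["entity_class"].isin(["source", "consumer"])
    if bad_class.any():
        rows = [int(i) + 2 for i in df.index[bad_class]]
        raise ParseError(
            f"{path.name}: entity_class must be source|consumer at rows {rows}"
        )
    for col in ("d13C", "d15N"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            rows = [int(i) + 2 for i in df.index[vals.isna()]]
            raise ParseError(f"{path.name}: non-numeric {col} at rows {rows}")
        df[col] = vals
    return df


# --------------------------------------------------------------------------
# manifest & pipeline config
# --------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record emitted before any results."""

    config: dict
    seed: int | None
    stage_seeds: dict[str, int]
    package_version: str
    input_digests: dict[str, str]
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, loadable from YAML/JSON."""

    simulate: bool = True
    preset: str = "paper-like"
    abundance_csv: str | None = None
    isotope_csv: str | None = None
    quadrat_area: float = 0.09
    log_base: float = 2.0
    t_test_variant: str = "student"
    alpha: float = 0.05
    delta_n: float = 2.5
    lam: float = 2.0
    primary_consumers: list[str] = field(default_factory=list)
    n_posterior_draws: int = 10_000
    overlap_resolution: int = 1000
    hdr_mass: float = 0.95
    mcmc: dict[str, int] = field(
        default_factory=lambda: {
            "chains": 4, "iterations": 20_000, "burn_in": 10_000, "thin": 10,
        }
    )
    tef: dict[str, float] = field(
        default_factory=lambda: {
            "mean_d15N": 2.5, "sd_d15N": 2.5, "mean_d13C": 0.47, "sd_d13C": 1.23,
        }
    )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def tef_obj(self) -> TEF:
        return TEF(**self.tef)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _child_seeds(seed: int | None, names: Sequence[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for n, c in zip(names, children)
    }


def run_full_pipeline(
    config: PipelineConfig | None = None,
    out_dir="results",
    seed: int | None = None,
    stages: Sequence[str] = ("community", "niche", "mixing"),
) -> dict[str, Any]:
    """Execute the study pipeline: community -> niche -> trophic -> mixing.

    With ``config.simulate`` the paper-like synthetic preset provides the
    inputs (written under ``out_dir/inputs`` alongside truth.json); otherwise
    the configured CSV paths are read. Returns a dict of result objects and
    output paths; all numeric outputs are deterministic given ``seed``.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(seed, ["simulate", "niche", "mixing"])
    report: dict[str, Any] = {"seed": seed, "stage_seeds": seeds}
    results: dict[str, Any] = {"out_dir": out, "report": report}

    digests = {}
    if not config.simulate:
        for p in (config.abundance_csv, config.isotope_csv):
            if p and Path(p).exists():
                digests[str(p)] = _sha256(p)

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=seed,
        stage_seeds=seeds,
        package_version=__version__,
        input_digests=digests,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )
    (out / "manifest.json").write_text(manifest.to_json())

    # ---- inputs ----------------------------------------------------------
    truth = None
    if config.simulate:
        log.info("simulate: generating %s preset", config.preset)
        if config.preset != "paper-like":
            raise ParseError(f"unknown preset {config.preset!r}")
        study = generate_study(paper_like_config(seed=seeds["simulate"]))
        tables = study.abundances
        iso = study.isotopes
        truth = study.truth
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        write_abundance_table(tables, inputs / "abundance.csv")
        iso.to_csv(inputs / "isotopes.csv", index=False)
        (inputs / "truth.json").write_text(json.dumps(truth, indent=2))
        primary = truth["primary_consumers"]
        results["truth"] = truth
    else:
        if not (config.abundance_csv and config.isotope_csv):
            raise ParseError(
                "pipeline stage inputs missing: provide abundance_csv and "
                "isotope_csv or set simulate: true"
            )
        tables = read_abundance_table(config.abundance_csv, config.quadrat_area)
        iso = read_isotope_table(config.isotope_csv)
        primary = config.primary_consumers

    sites = sorted({t.site for t in tables})

    # ---- community -------------------------------------------------------
    if "community" in stages:
        log.info("community: diversity and composition for %s", sites)
        div = replicate_diversity(tables, log_base=config.log_base)
        div.to_csv(out / "community_diversity.csv", index=False)
        density_table(tables).to_csv(out / "community_density.csv", index=False)

        comp = {
            site: trophic_group_composition(
                [t for t in tables if t.site == site]
            )
            for site in sites
        }
        pd.DataFrame(comp).rename_axis("trophic_group").to_csv(
            out / "community_composition.csv"
        )
        report["trophic_group_composition"] = comp

        site_taxa = {
            site: set().union(
                *(t.taxa_present() for t in tables if t.site == site)
            )
            for site in sites
        }
        if len(sites) == 2:
            a, b = sites
            report["sorensen"] = sorensen_index(site_taxa[a], site_taxa[b])
            tests = {}
            for metric in ("shannon_H", "pielou_J"):
                x = div.loc[div["site"] == a, metric].dropna()
                y = div.loc[div["site"] == b, metric].dropna()
                stat, p = two_sample_t_test(x, y, variant=config.t_test_variant)
                tests[metric] = {"statistic": stat, "p_value": p}
            report["diversity_t_tests"] = tests
        results["community_diversity"] = div

    # ---- niche + trophic levels -----------------------------------------
    if "niche" in stages:
        consumers = iso[iso["entity_class"] == "consumer"]
        niche_rows, tl_frames = {}, []
        site_specimens = {}
        for i, site in enumerate(sites):
            sub = consumers[consumers["site"] == site]
            spec_pts = sub[["d13C", "d15N"]].to_numpy()
            spp_pts = (
                sub.groupby("entity")[["d13C", "d15N"]].mean().to_numpy()
            )
            site_specimens[site] = spec_pts
            log.info("niche: site %s (%d specimens, %d species)",
                     site, len(spec_pts), len(spp_pts))
            ns = summarize_niche(
                spec_pts, spp_pts,
                n_draws=config.n_posterior_draws,
                seed=seeds["niche"] + i,
            )
            niche_rows[site] = ns.to_dict()
            pd.DataFrame({"SEA_posterior": ns.SEA_posterior}).to_csv(
                out / f"sea_posterior_{site}.csv", index=False
            )
            baseline = select_baseline(sub, primary, site=site)
            report.setdefault("baseline", {})[site] = baseline
            tl = trophic_level_table(
                iso, baseline, site=site,
                delta_n=config.delta_n, lam=config.lam,
            )
            tl_frames.append(tl)
        niche_df = pd.DataFrame(niche_rows).rename_axis("metric")
        niche_df.to_csv(out / "niche_summary.csv")
        pd.concat(tl_frames, ignore_index=True).to_csv(
            out / "trophic_levels.csv", index=False
        )
        if len(sites) == 2:
            a, b = sites
            report["seac_overlap"] = ellipse_overlap(
                site_specimens[a], site_specimens[b],
                resolution=config.overlap_resolution,
            )
        results["niche_summary"] = niche_df

    # ---- mixing ----------------------------------------------------------
    if "mixing" in stages:
        src = iso[iso["entity_class"] == "source"].rename(
            columns={"entity": "species", "source_group": "group"}
        )
        cons = iso[iso["entity_class"] == "consumer"]
        tef = config.tef_obj()
        mix_rows = []
        fit_idx = 0
        for site in sites:
            groups = aggregate_sources(
                src[src["site"] == site], alpha=config.alpha
            )
            for species, grp in cons[cons["site"] == site].groupby("entity"):
                if len(grp) < 3:
                    log.info("mixing: skipping %s at %s (n=%d < 3)",
                             species, site, len(grp))
                    continue
                log.info("mixing: %s at %s vs %d sources",
                         species, site, len(groups))
                model = MixingModel(
                    grp[["d13C", "d15N"]].to_numpy(), groups, tef=tef
                )
                res = model.fit(
                    seed=seeds["mixing"] + fit_idx, **config.mcmc
                )
                fit_idx += 1
                summ = res.summary(mass=config.hdr_mass).reset_index()
                summ.insert(0, "site", site)
                summ.insert(1, "species", species)
                mix_rows.append(summ)
        if mix_rows:
            mix_df = pd.concat(mix_rows, ignore_index=True)
            mix_df.to_csv(out / "mixing_results.csv", index=False)
            results["mixing_results"] = mix_df

    (out / "run_report.json").write_text(
        json.dumps(report, indent=2, default=float)
    )
    return results
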