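"""Synthetic two-site study generator with known ground truth.

Emulates a replicated two-site field design: a control site and a CO2-vent
("vent") site, each sampled with four 30 x 30 cm quadrats. Abundances are
drawn per taxon from a negative binomial (overdispersion is the norm for
quadrat counts; a Poisson limit is available). Basal-source isotope
signatures are Gaussian per species, with a uniform vent-ward depletion shift
applied to both isotopes at the vent site. Consumer specimens are drawn from
the mixing model's own likelihood given known diet proportions, so that diet
estimation can be tested in a closed loop.

Every generated dataset is accompanied by a ground-truth ledger (a plain
dict, serialisable to JSON) recording all true parameters; truth is never
mixed into the data tables themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import CommunityTable
from .exceptions import UndefinedInputError
from .mixing import TEF

DEFAULT_SITES = ("control", "vent")


@dataclass(frozen=True)
class TaxonSpec:
    """One taxon: trophic group and per-site mean density (ind m^-2).

    ``dispersion`` is the negative-binomial size parameter; ``None`` means
    Poisson counts (the infinite-dispersion limit).
    """

    label: str
    trophic_group: str
    density: Mapping[str, float]
    dispersion: float | None = 5.0


@dataclass(frozen=True)
class SourceSpec:
    """One basal-source species: ecological group and isotope distribution."""

    species: str
    group: str
    mean_d13C: float
    mean_d15N: float
    sd_d13C: float = 0.6
    sd_d15N: float = 0.3
    n_specimens: int = 5


@dataclass(frozen=True)
class ConsumerSpec:
    """One consumer species with true diet proportions over source groups."""

    species: str
    trophic_group: str
    diet: Mapping[str, float]
    n_specimens: int = 8
    residual_sd: float = 0.3
    primary_consumer: bool = False


@dataclass
class StudyConfig:
    """Complete specification of a synthetic two-site study.

    ``site_shift`` is the (d13C, d15N) shift added to every basal source at
    the vent site (negative = depletion). The seed is mandatory: the whole
    study is a deterministic function of the config.
    """

    seed: int
    taxa: Sequence[TaxonSpec]
    sources: Sequence[SourceSpec]
    consumers: Sequence[ConsumerSpec]
    tef: TEF = field(default_factory=TEF)
    sites: tuple[str, str] = DEFAULT_SITES
    vent_site: str = "vent"
    n_replicates_per_site: int = 4
    quadrat_area: float = 0.09
    site_shift: tuple[float, float] = (-2.5, -1.5)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise UndefinedInputError("seed is mandatory")
        if not self.quadrat_area > 0:
            raise UndefinedInputError("quadrat_area must be > 0")
        groups = {s.group for s in self.sources}
        for c in self.consumers:
            total = sum(c.diet.values())
            if abs(total - 1.0) > 1e-9:
                raise UndefinedInputError(
                    f"diet of {c.species!r} sums to {total}, not 1"
                )
            unknown = set(c.diet) - groups
            if unknown:
                raise UndefinedInputError(
                    f"diet of {c.species!r} references unknown source groups "
                    f"{sorted(unknown)}"
                )
        for t in self.taxa:
            if any(d < 0 for d in t.density.values()):
                raise UndefinedInputError(f"negative density for {t.label!r}")


@dataclass
class SyntheticStudy:
    """Generated study: abundance tables, isotope records, ground truth."""

    abundances: list[CommunityTable]
    isotopes: pd.DataFrame
    truth: dict


def _source_group_moments(
    config: StudyConfig, site: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group (mean, variance) of the site-shifted source mixture.

    Species within a group are weighted equally; the group variance includes
    the between-species spread so consumers are generated against the same
    aggregated sources the mixing stage will estimate.
    """
    shift = (
        np.array(config.site_shift)
        if site == config.vent_site
        else np.zeros(2)
    )
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    groups: dict[str, list[SourceSpec]] = {}
    for s in config.sources:
        groups.setdefault(s.group, []).append(s)
    for g, specs in groups.items():
        means = np.array(
            [[s.mean_d13C, s.mean_d15N] for s in specs]
        ) + shift
        sds = np.array([[s.sd_d13C, s.sd_d15N] for s in specs])
        gmean = means.mean(axis=0)
        gvar = (sds**2).mean(axis=0) + ((means - gmean) ** 2).mean(axis=0)
        out[g] = (gmean, gvar)
    return out


def generate_abundances(config: StudyConfig) -> list[CommunityTable]:
    """Draw one CommunityTable per site x replicate.

    Counts per taxon are negative binomial with mean density * quadrat_area
    and the taxon's dispersion (Poisson when dispersion is None). The stream
    is independent of `generate_isotopes` and deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    trophic = {t.label: t.trophic_group for t in config.taxa}
    tables = []
    for site in config.sites:
        for r in range(config.n_replicates_per_site):
            counts: dict[str, int] = {}
            for t in config.taxa:
                m = t.density.get(site, 0.0) * config.quadrat_area
                if m <= 0:
                    counts[t.label] = 0
                elif t.dispersion is None or not np.isfinite(t.dispersion):
                    counts[t.label] = int(rng.poisson(m))
                else:
                    k = float(t.dispersion)
                    counts[t.label] = int(
                        rng.negative_binomial(k, k / (k + m))
                    )
            tables.append(
                CommunityTable(
                    site=site,
                    replicate=f"R{r + 1}",
                    quadrat_area=config.quadrat_area,
                    counts=counts,
                    trophic_group=dict(trophic),
                )
            )
    return tables


def generate_isotopes(config: StudyConfig) -> tuple[pd.DataFrame, dict]:
    """Draw source and consumer isotope records plus the ground-truth ledger.

    Source specimens are Normal around the (site-shifted) species means.
    Consumer specimens are drawn from the mixing likelihood: mean
    sum_k p_k mu_kj + TEF_mu_j and variance
    sum_k p_k^2 (var_kj + TEF_sd_j^2) + residual_sd^2 per isotope, using the
    aggregated group moments of the same site.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    tef_mu = np.array([config.tef.mean_d13C, config.tef.mean_d15N])
    tef_var = np.array([config.tef.sd_d13C**2, config.tef.sd_d15N**2])
    rows = []
    truth: dict = {
        "seed": int(config.seed),
        "sites": list(config.sites),
        "vent_site": config.vent_site,
        "site_shift": {"d13C": config.site_shift[0], "d15N": config.site_shift[1]},
        "tef": {
            "mean_d13C": config.tef.mean_d13C,
            "sd_d13C": config.tef.sd_d13C,
            "mean_d15N": config.tef.mean_d15N,
            "sd_d15N": config.tef.sd_d15N,
        },
        "source_species_means": {},
        "source_group_means": {},
        "diet_proportions": {
            c.species: dict(c.diet) for c in config.consumers
        },
        "consumer_mean_signatures": {},
        "primary_consumers": [
            c.species for c in config.consumers if c.primary_consumer
        ],
        "baseline": {},
        "trophic_group_weights": {},
    }

    for site in config.sites:
        shift = (
            np.array(config.site_shift)
            if site == config.vent_site
            else np.zeros(2)
        )
        truth["source_species_means"][site] = {
            s.species: {
                "d13C": s.mean_d13C + shift[0],
                "d15N": s.mean_d15N + shift[1],
            }
            for s in config.sources
        }
        gm = _source_group_moments(config, site)
        truth["source_group_means"][site] = {
            g: {"d13C": m[0], "d15N": m[1]} for g, (m, _) in gm.items()
        }

        for s in config.sources:
            mu = np.array([s.mean_d13C, s.mean_d15N]) + shift
            sd = np.array([s.sd_d13C, s.sd_d15N])
            vals = rng.normal(mu, sd, size=(s.n_specimens, 2))
            for i, (c13, n15) in enumerate(vals, start=1):
                rows.append(
                    {
                        "entity": s.species,
                        "entity_class": "source",
                        "source_group": s.group,
                        "trophic_group": "",
                        "site": site,
                        "specimen": f"{s.species}-{site}-{i}",
                        "d13C": float(c13),
                        "d15N": float(n15),
                    }
                )

        sigs = {}
        for c in config.consumers:
            p = np.array([c.diet.get(g, 0.0) for g in gm])
            mus = np.array([gm[g][0] for g in gm])
            gvars = np.array([gm[g][1] for g in gm])
            mean = p @ mus + tef_mu
            var = (p**2) @ (gvars + tef_var) + c.residual_sd**2
            sigs[c.species] = {"d13C": float(mean[0]), "d15N": float(mean[1])}
            vals = rng.normal(mean, np.sqrt(var), size=(c.n_specimens, 2))
            for i, (c13, n15) in enumerate(vals, start=1):
                rows.append(
                    {
                        "entity": c.species,
                        "entity_class": "consumer",
                        "source_group": "",
                        "trophic_group": c.trophic_group,
                        "site": site,
                        "specimen": f"{c.species}-{site}-{i}",
                        "d13C": float(c13),
                        "d15N": float(n15),
                    }
                )
        truth["consumer_mean_signatures"][site] = sigs

        primaries = [c for c in config.consumers if c.primary_consumer]
        if primaries:
            truth["baseline"][site] = min(
                primaries, key=lambda c: sigs[c.species]["d15N"]
            ).species

        dens = {}
        for t in config.taxa:
            d = t.density.get(site, 0.0)
            dens[t.trophic_group] = dens.get(t.trophic_group, 0.0) + d
        total = sum(dens.values())
        truth["trophic_group_weights"][site] = {
            g: 100.0 * v / total for g, v in dens.items()
        }

    return pd.DataFrame(rows), truth


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate abundances, isotopes and the truth ledger for one config."""
    abundances = generate_abundances(config)
    isotopes, truth = generate_isotopes(config)
    return SyntheticStudy(abundances=abundances, isotopes=isotopes, truth=truth)


# --------------------------------------------------------------------------
# paper-like preset
# --------------------------------------------------------------------------

# (label, trophic group, relative weight control, relative weight vent)
# 11 taxa occur at both sites, 21 only at the control, 12 only at the vent —
# a gastropod-dominated control and a polychaete/peracarid-dominated vent.
_SHARED_TAXA = [
    ("Bittium reticulatum", "herbivore/detritivore", 10.0, 0.4),
    ("Platynereis cfr dumerilii", "herbivore", 2.0, 10.0),
    ("Chondrochelia savignyi", "herbivore/detritivore", 3.0, 8.0),
    ("Phtisica marina", "omnivore/detritivore", 2.0, 1.0),
    ("Caprella acanthifera", "herbivore/detritivore", 1.5, 4.0),
    ("Dexaminidae sp.", "herbivore/detritivore", 2.0, 3.0),
    ("Cerithium rusticum", "herbivore", 3.0, 1.0),
    ("Hippolytidae sp.", "herbivore/detritivore", 1.0, 1.0),
    ("Ischyroceridae sp.", "herbivore/detritivore", 1.0, 3.0),
    ("Tanais dulongii", "herbivore/detritivore", 1.0, 2.0),
    ("Gammarella fucicola", "herbivore/detritivore", 1.5, 2.0),
]
_CONTROL_ONLY_TAXA = [
    ("Rissoa ventricosa", "herbivore/detritivore", 3.0),
    ("Gibbula ardens", "herbivore", 2.0),
    ("Jujubinus exasperatus", "herbivore", 1.5),
    ("Tricolia pullus", "herbivore/detritivore", 2.0),
    ("Alvania lineata", "herbivore/detritivore", 1.5),
    ("Ocinebrina edwardsii", "carnivore", 2.0),
    ("Nassarius incrassatus", "carnivore", 1.5),
    ("Haminoea navicula", "herbivore", 1.0),
    ("Syllis prolifera", "carnivore", 2.5),
    ("Nereiphylla rubiginosa", "carnivore", 1.0),
    ("Nephtys sp.", "carnivore", 0.8),
    ("Polyophthalmus pictus", "omnivore/detritivore", 1.0),
    ("Amphipholis squamata", "omnivore/detritivore", 0.5),
    ("Apseudopsis latreillii", "herbivore/detritivore", 1.5),
    ("Leptochelia savignyi", "herbivore/detritivore", 1.0),
    ("Ampithoe ramondi", "herbivore", 1.5),
    ("Hyale schmidtii", "herbivore", 1.0),
    ("Microdeutopus gryllotalpa", "herbivore/detritivore", 1.5),
    ("Stenothoe monoculoides", "filter-feeder", 0.5),
    ("Mytilaster minimus", "filter-feeder", 0.8),
    ("Palaemon elegans", "carnivore", 0.7),
]
_VENT_ONLY_TAXA = [
    ("Platynereis massiliensis", "herbivore", 3.0),
    ("Amphiglena mediterranea", "filter-feeder", 1.0),
    ("Exogone naidina", "carnivore", 0.5),
    ("Caprella grandimana", "herbivore/detritivore", 2.0),
    ("Elasmopus rapax", "herbivore/detritivore", 2.0),
    ("Lysianassa costae", "omnivore/detritivore", 0.8),
    ("Gammaropsis maculata", "herbivore/detritivore", 1.5),
    ("Dynamene bidentata", "herbivore", 1.0),
    ("Idotea balthica", "herbivore", 1.5),
    ("Cymodoce truncata", "herbivore/detritivore", 1.0),
    ("Atylus guttatus", "herbivore/detritivore", 1.0),
    ("Sphaeroma serratum", "herbivore/detritivore", 1.0),
]

# printed trophic-group percentages of individuals and pooled totals
_GROUP_WEIGHTS = {
    "control": {
        "herbivore/detritivore": 58.4,
        "carnivore": 24.7,
        "herbivore": 14.6,
        "omnivore/detritivore": 1.5,
        "filter-feeder": 0.8,
    },
    "vent": {
        "herbivore/detritivore": 72.9,
        "herbivore": 25.5,
        "filter-feeder": 1.1,
        "omnivore/detritivore": 0.4,
        "carnivore": 0.1,
    },
}
# total individuals over 4 quadrats (0.36 m^2): 384 control, 879 vent
_TOTAL_DENSITY = {"control": 384 / 0.36, "vent": 879 / 0.36}

_SOURCES = [
    SourceSpec("Cymodocea nodosa", "seagrasses", -8.5, 3.6),
    SourceSpec("Zostera noltei", "seagrasses", -8.9, 3.5),
    SourceSpec("Cystoseira compressa", "algae", -14.0, 2.4),
    SourceSpec("Dictyota dichotoma", "algae", -14.6, 2.3),
    SourceSpec("Epiphytes", "epiphytes", -17.5, 1.3),
    SourceSpec("SOM", "SOM", -21.0, 0.3),
]

_CONSUMERS = [
    ConsumerSpec(
        "Dexaminidae sp.", "herbivore/detritivore",
        {"seagrasses": 0.05, "algae": 0.10, "epiphytes": 0.25, "SOM": 0.60},
        n_specimens=20, primary_consumer=True,
    ),
    ConsumerSpec(
        "Gammarella fucicola", "herbivore/detritivore",
        {"seagrasses": 0.15, "algae": 0.55, "epiphytes": 0.20, "SOM": 0.10},
        n_specimens=20, primary_consumer=True,
    ),
    ConsumerSpec(
        "Bittium reticulatum", "herbivore/detritivore",
        {"seagrasses": 0.25, "algae": 0.25, "epiphytes": 0.25, "SOM": 0.25},
    ),
    ConsumerSpec(
        "Platynereis cfr dumerilii", "herbivore",
        {"seagrasses": 0.30, "algae": 0.20, "epiphytes": 0.15, "SOM": 0.35},
    ),
    ConsumerSpec(
        "Chondrochelia savignyi", "herbivore/detritivore",
        {"seagrasses": 0.15, "algae": 0.35, "epiphytes": 0.15, "SOM": 0.35},
    ),
    ConsumerSpec(
        "Cerithium rusticum", "herbivore",
        {"seagrasses": 0.30, "algae": 0.30, "epiphytes": 0.25, "SOM": 0.15},
    ),
    ConsumerSpec(
        "Hippolytidae sp.", "herbivore/detritivore",
        {"seagrasses": 0.10, "algae": 0.35, "epiphytes": 0.30, "SOM": 0.25},
    ),
    ConsumerSpec(
        "Caprella acanthifera", "herbivore/detritivore",
        {"seagrasses": 0.20, "algae": 0.25, "epiphytes": 0.30, "SOM": 0.25},
    ),
]


def _build_paper_like_taxa() -> list[TaxonSpec]:
    """Convert relative weights into absolute densities matching the printed
    trophic-group percentages and pooled totals at each site."""
    entries: list[tuple[str, str, dict[str, float]]] = []
    for label, group, wc, wv in _SHARED_TAXA:
        entries.append((label, group, {"control": wc, "vent": wv}))
    for label, group, wc in _CONTROL_ONLY_TAXA:
        entries.append((label, group, {"control": wc}))
    for label, group, wv in _VENT_ONLY_TAXA:
        entries.append((label, group, {"vent": wv}))

    group_sums: dict[tuple[str, str], float] = {}
    for _, group, w in entries:
        for site, wt in w.items():
            group_sums[(site, group)] = group_sums.get((site, group), 0.0) + wt

    taxa = []
    for label, group, w in entries:
        density = {}
        for site, wt in w.items():
            target = (
                _GROUP_WEIGHTS[site][group] / 100.0 * _TOTAL_DENSITY[site]
            )
            density[site] = wt / group_sums[(site, group)] * target
        taxa.append(TaxonSpec(label=label, trophic_group=group, density=density))
    return taxa


def paper_like_config(seed: int = 0) -> StudyConfig:
    """The packaged two-site preset.

    Mirrors the published study's structure: 32 control / 23 vent taxa with
    11 shared; printed trophic-group percentages; control source d13C between
    -21 and -8.5 permil and d15N between 0.3 and 3.6 permil; a uniform
    vent-ward depletion of (-2.5, -1.5) permil on all sources; herbivore TEFs
    2.5 +/- 2.5 (d15N) and 0.47 +/- 1.23 (d13C); consumers drawn from known
    diets over the four aggregated source groups.
    """
    return StudyConfig(
        seed=seed,
        taxa=_build_paper_like_taxa(),
        sources=list(_SOURCES),
        consumers=list(_CONSUMERS),
        site_shift=(-2.5, -1.5),
    )
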