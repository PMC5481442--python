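"""Synthetic study generator: determinism, distributional targets, truth."""

import numpy as np
import pandas as pd
import pytest

from isofoodweb.community import trophic_group_composition
from isofoodweb.exceptions import UndefinedInputError
from isofoodweb.mixing import TEF
from isofoodweb.niche import select_baseline
from isofoodweb.synthetic import (
    ConsumerSpec,
    SourceSpec,
    StudyConfig,
    TaxonSpec,
    generate_abundances,
    generate_isotopes,
    generate_study,
    paper_like_config,
)


def group_percentage_se(cfg, site):
    """Analytic SE (percentage points) of each group's share of individuals.

    Counts are negative binomial per taxon and quadrat with variance
    m + m^2/k; the share's variance follows by the delta method on
    p = C_group / (C_group + C_other) with independent group totals.
    """
    R, A = cfg.n_replicates_per_site, cfg.quadrat_area
    groups = {}
    for t in cfg.taxa:
        m = t.density.get(site, 0.0) * A
        if m <= 0:
            continue
        v = m + m * m / t.dispersion if t.dispersion else m
        gm, gv = groups.get(t.trophic_group, (0.0, 0.0))
        groups[t.trophic_group] = (gm + m, gv + v)
    C = {g: R * m for g, (m, _) in groups.items()}
    V = {g: R * v for g, (_, v) in groups.items()}
    N = sum(C.values())
    out = {}
    for g in groups:
        c, o = C[g], N - C[g]
        vo = sum(V[h] for h in groups if h != g)
        out[g] = 100.0 * np.sqrt((o * o * V[g] + c * c * vo) / N**4)
    return out


def tiny_config(seed=0, **overrides):
    defaults = dict(
        seed=seed,
        taxa=[
            TaxonSpec("snail", "herbivore", {"control": 100.0, "vent": 10.0}),
            TaxonSpec("worm", "carnivore", {"control": 20.0, "vent": 50.0}),
        ],
        sources=[
            SourceSpec("plant", "plants", -12.0, 3.0),
            SourceSpec("mud", "detritus", -22.0, 0.0),
        ],
        consumers=[
            ConsumerSpec("snail", "herbivore",
                         {"plants": 0.8, "detritus": 0.2}, n_specimens=6),
        ],
    )
    defaults.update(overrides)
    return StudyConfig(**defaults)


class TestDeterminism:
    def test_same_config_same_study(self):
        s1 = generate_study(paper_like_config(seed=42))
        s2 = generate_study(paper_like_config(seed=42))
        pd.testing.assert_frame_equal(s1.isotopes, s2.isotopes)
        assert s1.truth == s2.truth
        for a, b in zip(s1.abundances, s2.abundances):
            assert a.counts == b.counts

    def test_different_seed_differs(self):
        s1 = generate_study(paper_like_config(seed=1))
        s2 = generate_study(paper_like_config(seed=2))
        assert not s1.isotopes["d13C"].equals(s2.isotopes["d13C"])


class TestAbundances:
    def test_poisson_limit_replicate_mean(self):
        cfg = tiny_config(
            taxa=[TaxonSpec("snail", "herbivore", {"control": 100.0},
                            dispersion=None)],
            n_replicates_per_site=1000,
            sites=("control", "control2"),
        )
        tables = generate_abundances(cfg)
        counts = [t.counts["snail"] for t in tables if t.site == "control"]
        # mean 100 ind/m2 * 0.09 m2 = 9 per quadrat
        assert np.mean(counts) == pytest.approx(9.0, abs=0.35)

    def test_zero_density_taxon_all_zero(self):
        cfg = tiny_config(
            taxa=[TaxonSpec("ghost", "herbivore", {"control": 0.0})]
        )
        tables = generate_abundances(cfg)
        assert all(t.counts["ghost"] == 0 for t in tables)

    def test_negative_binomial_overdispersed(self):
        cfg = tiny_config(
            taxa=[TaxonSpec("snail", "herbivore", {"control": 500.0},
                            dispersion=2.0)],
            n_replicates_per_site=500,
        )
        counts = np.array(
            [t.counts["snail"] for t in generate_abundances(cfg)
             if t.site == "control"]
        )
        m = counts.mean()
        assert counts.var() > 1.5 * m  # variance well above the Poisson line


class TestIsotopes:
    def test_vent_shift_applied_exactly_in_truth(self):
        cfg = tiny_config(site_shift=(-3.0, -1.5))
        _, truth = generate_isotopes(cfg)
        for sp in ("plant", "mud"):
            c = truth["source_species_means"]["control"][sp]
            v = truth["source_species_means"]["vent"][sp]
            assert v["d13C"] - c["d13C"] == pytest.approx(-3.0)
            assert v["d15N"] - c["d15N"] == pytest.approx(-1.5)

    def test_vent_source_specimens_depleted_on_average(self):
        iso, truth = generate_isotopes(paper_like_config(seed=5))
        src = iso[iso.entity_class == "source"]
        for col, shift in (("d13C", -2.5), ("d15N", -1.5)):
            diff = (
                src[src.site == "vent"][col].mean()
                - src[src.site == "control"][col].mean()
            )
            assert diff == pytest.approx(shift, abs=0.5)

    def test_pure_diet_zero_variance_degenerate(self):
        cfg = tiny_config(
            sources=[
                SourceSpec("plant", "plants", -12.0, 3.0, sd_d13C=0, sd_d15N=0),
                SourceSpec("mud", "detritus", -22.0, 0.0, sd_d13C=0, sd_d15N=0),
            ],
            consumers=[
                ConsumerSpec("snail", "herbivore",
                             {"plants": 1.0, "detritus": 0.0},
                             n_specimens=4, residual_sd=0.0),
            ],
            tef=TEF(sd_d15N=0.0, sd_d13C=0.0),
        )
        iso, _ = generate_isotopes(cfg)
        snail = iso[(iso.entity == "snail") & (iso.site == "control")]
        assert np.allclose(snail["d13C"], -12.0 + 0.47)
        assert np.allclose(snail["d15N"], 3.0 + 2.5)

    def test_baseline_truth_is_lowest_designated_primary(self):
        iso, truth = generate_isotopes(paper_like_config(seed=3))
        cons = iso[iso.entity_class == "consumer"]
        for site in ("control", "vent"):
            selected = select_baseline(
                cons[cons.site == site], truth["primary_consumers"], site=site
            )
            assert selected == truth["baseline"][site]


class TestPaperLikePreset:
    def test_taxon_set_structure(self):
        cfg = paper_like_config()
        control = {t.label for t in cfg.taxa if t.density.get("control", 0) > 0}
        vent = {t.label for t in cfg.taxa if t.density.get("vent", 0) > 0}
        assert (len(control), len(vent)) == (32, 23)
        assert len(control & vent) == 11

    def test_group_weights_recovered_within_sampling_error(self):
        cfg = paper_like_config(seed=17)
        study = generate_study(cfg)
        for site in ("control", "vent"):
            comp = trophic_group_composition(
                [t for t in study.abundances if t.site == site]
            )
            ses = group_percentage_se(cfg, site)
            for g, expected in study.truth["trophic_group_weights"][site].items():
                tol = 3.5 * ses[g] + 0.2
                assert comp.get(g, 0.0) == pytest.approx(expected, abs=tol)

    def test_diets_sum_to_one(self):
        cfg = paper_like_config()
        for c in cfg.consumers:
            assert sum(c.diet.values()) == pytest.approx(1.0, abs=1e-9)


class TestValidation:
    def test_bad_diet_rejected(self):
        with pytest.raises(UndefinedInputError):
            tiny_config(
                consumers=[
                    ConsumerSpec("snail", "herbivore",
                                 {"plants": 0.5, "detritus": 0.2})
                ]
            )

    def test_unknown_source_group_rejected(self):
        with pytest.raises(UndefinedInputError):
            tiny_config(
                consumers=[
                    ConsumerSpec("snail", "herbivore", {"lava": 1.0})
                ]
            )

    def test_negative_density_rejected(self):
        with pytest.raises(UndefinedInputError):
            tiny_config(
                taxa=[TaxonSpec("snail", "herbivore", {"control": -1.0})]
            )
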