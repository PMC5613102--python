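"""Ground-truth generators and the conversion-recovery theorem."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vlcfa.conversion_stats import compare_groups, sfa_percentages, stepwise_conversions
from vlcfa.fa_model import parse_fa
from vlcfa.qpcr_quant import StandardCurve
from vlcfa.synthetic_data import (
    CascadeSimConfig,
    QpcrSimConfig,
    SfaSimConfig,
    noiseless_cascade_amounts,
    simulate_cascade_areas,
    simulate_qpcr,
    simulate_sfa_profiles,
)

SUB = parse_fa("18:4n-3")


class TestCascadeSimulator:
    def test_closed_form_node_amounts(self):
        amounts = noiseless_cascade_amounts((0.5, 0.25), a0=100.0)
        assert amounts == pytest.approx([50.0, 37.5, 12.5])

    def test_noiseless_recovery_of_fractions(self):
        cfg = CascadeSimConfig(SUB, (0.5, 0.25), a0=100.0, seed=3)
        table = simulate_cascade_areas(cfg)
        res = stepwise_conversions(table, cfg.cascade)
        assert [r.conversion for r in res] == pytest.approx([50.0, 25.0], abs=1e-12)

    def test_same_seed_bit_identical(self):
        cfg = CascadeSimConfig(SUB, (0.4, 0.7, 0.1), noise_sigma=0.2, seed=11)
        a = simulate_cascade_areas(cfg)
        b = simulate_cascade_areas(cfg)
        assert a == b

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            CascadeSimConfig(SUB, (0.5, 1.0))
        with pytest.raises(ValueError):
            CascadeSimConfig(SUB, (-0.1,))

    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(0.01, 0.99)),
            min_size=1,
            max_size=9,
        ),
        st.floats(1.0, 1e4),
    )
    def test_mass_conservation_and_recovery_theorem(self, fractions, a0):
        amounts = noiseless_cascade_amounts(fractions, a0)
        assert float(amounts.sum()) == pytest.approx(a0, rel=1e-12)
        cfg = CascadeSimConfig(SUB, tuple(fractions), a0=a0, seed=0)
        res = stepwise_conversions(simulate_cascade_areas(cfg), cfg.cascade)
        for r, e in zip(res, fractions):
            expected = 100.0 * e
            if r.not_detected:
                # only reachable when all flux upstream was exactly consumed
                assert any(f == 0.0 for f in fractions[: r.step_index])
            else:
                assert r.conversion == pytest.approx(expected, abs=1e-9)

    def test_lod_censoring_never_inflates_interior_values(self, rng):
        # Removing signal can only push a step to N.D., to 100 (substrate
        # censored away) or monotonically down toward 0 — never upward to a
        # new interior value.
        for _ in range(100):
            k = rng.integers(2, 7)
            fractions = tuple(rng.uniform(0, 0.95, size=k))
            lod = rng.uniform(0, 20)
            cfg = CascadeSimConfig(SUB, fractions, a0=100.0, seed=int(rng.integers(2**31)))
            base = stepwise_conversions(simulate_cascade_areas(cfg), cfg.cascade)
            cfg_lod = CascadeSimConfig(SUB, fractions, a0=100.0, lod=lod,
                                       seed=cfg.seed)
            censored = stepwise_conversions(simulate_cascade_areas(cfg_lod), cfg_lod.cascade)
            for b, c in zip(base, censored):
                if b.not_detected:
                    assert c.not_detected
                elif not c.not_detected:
                    assert (
                        c.conversion == 100.0
                        or c.conversion <= b.conversion + 1e-9
                    )

    def test_downstream_flux_nonincreasing(self, rng):
        fractions = tuple(rng.uniform(0, 0.95, size=6))
        cfg = CascadeSimConfig(SUB, fractions, noise_sigma=0.1, seed=5)
        table = simulate_cascade_areas(cfg)
        # noiseless cumulative flux is monotone by construction
        amounts = noiseless_cascade_amounts(fractions, cfg.a0)
        tails = amounts[::-1].cumsum()[::-1]
        assert np.all(np.diff(tails) <= 1e-12)
        assert set(table.areas) == set(cfg.cascade.members)


class TestSfaSimulator:
    baseline = {parse_fa("24:0"): 1.2, parse_fa("26:0"): 23.5, parse_fa("28:0"): 1.0}

    def test_null_boost_identical_distributions(self):
        cfg = SfaSimConfig(self.baseline, {"transgenic": {}}, n_replicates=3,
                           noise_cv=0.0, seed=1)
        tables = simulate_sfa_profiles(cfg)
        by_treatment = {}
        for t in tables:
            by_treatment.setdefault(t.treatment, []).append(t.areas)
        assert by_treatment["control"] == by_treatment["transgenic"]

    def test_boost_shifts_mass_and_profiles_renormalize(self):
        boost_fa = parse_fa("28:0")
        cfg = SfaSimConfig(self.baseline, {"elovl4a": {boost_fa: 4.0}},
                           n_replicates=4, noise_cv=0.05, seed=7)
        tables = simulate_sfa_profiles(cfg)
        profiles = [sfa_percentages(t) for t in tables]
        for p in profiles:
            assert sum(p.percents.values()) == pytest.approx(100.0, abs=1e-9)
        mean_ctrl = np.mean([p.percents[boost_fa] for p in profiles if p.treatment == "control"])
        mean_tg = np.mean([p.percents[boost_fa] for p in profiles if p.treatment == "elovl4a"])
        assert mean_tg > 2 * mean_ctrl

    def test_boosted_fa_gets_distinct_letter(self):
        boost_fa = parse_fa("28:0")
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SfaSimConfig(self.baseline, {"elovl4a": {boost_fa: 4.0}},
                               n_replicates=4, noise_cv=0.05, seed=seed)
            profiles = [sfa_percentages(t) for t in simulate_sfa_profiles(cfg)]
            cmp = compare_groups(profiles, alpha=0.05)
            letters = cmp.variables[boost_fa].letters
            if not set(letters["control"]) & set(letters["elovl4a"]):
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_negative_boost_rejected(self):
        with pytest.raises(ValueError):
            SfaSimConfig(self.baseline, {"t": {parse_fa("28:0"): -1.0}})


class TestQpcrSimulator:
    curves = {"tgt": StandardCurve(-3.4, 38.0, 1.0), "ref": StandardCurve(-3.2, 33.0, 1.0)}

    def test_dilution_points_exact(self):
        cfg = QpcrSimConfig(self.curves, {"brain": {"tgt": 1e5, "ref": 1e7}}, seed=1)
        dil, _ = simulate_qpcr(cfg)
        for row in dil.itertuples():
            assert row.cq == pytest.approx(self.curves[row.gene].cq(row.copies), abs=1e-12)

    def test_noiseless_pipeline_recovers_true_ratios(self):
        from vlcfa.qpcr_quant import fit_standard_curve, normalized_ratios
        from vlcfa.io_utils import read_qpcr_measurements

        truth = {"brain": {"tgt": 2e5, "ref": 4e7}, "liver": {"tgt": 1e3, "ref": 4e7}}
        cfg = QpcrSimConfig(self.curves, truth, cq_sd=0.0, seed=2)
        dil, meas = simulate_qpcr(cfg)
        curves = {
            g: fit_standard_curve(list(zip(d["copies"], d["cq"])))
            for g, d in dil.groupby("gene")
        }
        from vlcfa.qpcr_quant import QpcrMeasurement

        ms = [
            QpcrMeasurement(r.tissue, r.sex, r.fish_id, r.gene, (r.cq_rep1, r.cq_rep2))
            for r in meas.itertuples()
        ]
        for r in normalized_ratios(ms, curves, "tgt", "ref"):
            expected = truth[r.tissue]["tgt"] / truth[r.tissue]["ref"]
            assert r.ratio == pytest.approx(expected, rel=1e-6)

    def test_duplicates_and_determinism(self):
        cfg = QpcrSimConfig(self.curves, {"brain": {"tgt": 1e5, "ref": 1e7}},
                            cq_sd=0.3, seed=9)
        _, a = simulate_qpcr(cfg)
        _, b = simulate_qpcr(cfg)
        assert a.equals(b)
        assert {"cq_rep1", "cq_rep2"} <= set(a.columns)
        assert (a.cq_rep1 != a.cq_rep2).any()

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            QpcrSimConfig({"tgt": StandardCurve(3.4, 38.0, 1.0)}, {})
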