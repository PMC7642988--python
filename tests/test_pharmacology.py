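"""Hill block curves, fitting, independent-site combination, and the
beta-adrenergic parameter transformation."""

import json
from importlib import resources

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiopop import pharmacology as ph
from cardiopop.synthetic import gen_hill_dataset


class TestHillInhibition:
    @pytest.mark.parametrize("h", [0.5, 1.0, 2.7])
    def test_half_block_at_ic50_for_any_hill_coefficient(self, h):
        hp = ph.HillParams(ic50_uM=7.3, hill=h)
        assert ph.hill_inhibition(7.3, hp) == pytest.approx(0.5)

    def test_zero_dose_gives_zero_block(self):
        assert ph.hill_inhibition(0.0, ph.HillParams(10.0, 1.3)) == 0.0

    def test_monotone_nondecreasing(self):
        hp = ph.HillParams(ic50_uM=5.0, hill=1.7)
        c = np.logspace(-3, 3, 100)
        b = ph.hill_inhibition(c, hp)
        assert np.all(np.diff(b) >= 0)
        assert np.all((b >= 0) & (b < 1))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ph.hill_inhibition(-1.0, ph.HillParams(10.0))

    @pytest.mark.parametrize("bad", [{"ic50_uM": 0.0}, {"ic50_uM": 1.0, "hill": -1.0}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ph.HillParams(**bad)


class TestFitHill:
    def test_noiseless_round_trip_is_exact(self):
        truth = ph.HillParams(ic50_uM=10.0, hill=1.0)
        c = np.logspace(-1, 3, 9)
        pts = np.column_stack([c, ph.hill_inhibition(c, truth)])
        fit, rss = ph.fit_hill(pts)
        assert fit.ic50_uM == pytest.approx(truth.ic50_uM, rel=1e-6)
        assert fit.hill == pytest.approx(truth.hill, rel=1e-6)
        assert rss < 1e-12

    def test_recovery_from_noisy_data(self):
        """Monte-Carlo over 100 seeds with sigma = 0.02 measurement noise:
        the IC50 recovery distribution is tight (median < 5%), nearly all
        replicates land within 10%, and none strays beyond 25%."""
        truth = ph.HillParams(ic50_uM=10.0, hill=1.0)
        c = np.logspace(-1, 3, 9)
        errs = []
        for seed in range(100):
            pts, _ = gen_hill_dataset(truth, c, noise_sd=0.02, seed=seed)
            fit, _ = ph.fit_hill(pts)
            errs.append(abs(fit.ic50_uM - truth.ic50_uM) / truth.ic50_uM)
        errs = np.array(errs)
        assert np.median(errs) < 0.05
        assert np.mean(errs < 0.10) >= 0.90
        assert errs.max() < 0.25

    def test_fitted_curve_interpolates_monotonically_between_straddling_points(self):
        pts = [(1.0, 0.2), (10.0, 0.8), (3.0, 0.5)]
        fit, _ = ph.fit_hill(pts)
        b1 = ph.hill_inhibition(1.0, fit)
        b2 = ph.hill_inhibition(10.0, fit)
        assert b1 < 0.5 < b2

    @pytest.mark.parametrize(
        "pts, match",
        [
            ([(1, 0.1), (2, 0.2)], ">= 3"),
            ([(5, 0.1), (5, 0.2), (5, 0.3)], "distinct"),
            ([(1, 0.0), (2, 0.0), (4, 0.0)], "unidentifiable"),
        ],
    )
    def test_degenerate_inputs_rejected(self, pts, match):
        with pytest.raises(ValueError, match=match):
            ph.fit_hill(pts)


class TestCombinedBlock:
    def test_worked_example(self):
        assert ph.combined_block([0.3, 0.5]) == pytest.approx(0.65)

    def test_zero_is_identity_and_one_absorbs(self):
        assert ph.combined_block([0.42, 0.0]) == pytest.approx(0.42)
        assert ph.combined_block([1.0, 0.3]) == pytest.approx(1.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_commutative_associative_bounded(self, blocks):
        total = ph.combined_block(blocks)
        assert 0.0 <= total <= 1.0
        assert total == pytest.approx(ph.combined_block(list(reversed(blocks))))
        # associativity: fold pairwise in any grouping
        left = ph.combined_block([ph.combined_block(blocks[:2]), *blocks[2:]])
        assert total == pytest.approx(left)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ph.combined_block([0.5, 1.2])


class TestApplyDrugs:
    def test_empty_list_is_identity(self, base):
        out = ph.apply_drugs(base, [])
        assert out.scale == base.scale
        assert out is not base

    def test_single_channel_locality(self, base):
        drug = ph.DrugSpec("X", 10.0, {"IKr": ph.HillParams(ic50_uM=10.0, hill=1.0)})
        out = ph.apply_drugs(base, [drug])
        assert out.scale["IKr"] == pytest.approx(0.5)
        assert set(out.scale) == {"IKr"}
        assert base.scale == {}  # input untouched

    def test_sequential_equals_joint_application(self, base, cq, azm):
        joint = ph.apply_drugs(base, [cq, azm])
        seq = ph.apply_drugs(ph.apply_drugs(base, [cq]), [azm])
        for ch in joint.scale:
            assert joint.scale[ch] == pytest.approx(seq.scale[ch], rel=1e-12)

    def test_packaged_table_ikr_multiplier_is_product_of_unblocked_fractions(self, base, cq, azm):
        with resources.files("cardiopop").joinpath("data", "drug_blocks.json").open() as fh:
            cfg = json.load(fh)["drugs"]

        def unblocked(drug_cfg):
            c = drug_cfg["concentration_uM"]
            e = drug_cfg["channels"]["IKr"]
            return 1.0 - c ** e["hill"] / (e["ic50_uM"] ** e["hill"] + c ** e["hill"])

        expected = unblocked(cfg["CQ"]) * unblocked(cfg["AZM"])
        out = ph.apply_drugs(base, [cq, azm])
        assert out.scale["IKr"] == pytest.approx(expected, rel=1e-12)

    def test_unknown_channel_rejected_in_spec(self):
        with pytest.raises(ValueError, match="not a drug target"):
            ph.DrugSpec("X", 1.0, {"INaK": ph.HillParams(10.0)})


class TestIsoEffects:
    def test_zero_fraction_is_identity(self, base, iso):
        out = ph.apply_iso(base, iso.with_fraction(0.0))
        assert out.scale == base.scale
        assert out.dv_act_mV == base.dv_act_mV

    def test_multiplier_interpolation_is_monotone(self, base, iso):
        m_half = ph.apply_iso(base, iso.with_fraction(0.5)).scale["IKs"]
        m_full = ph.apply_iso(base, iso.with_fraction(1.0)).scale["IKs"]
        assert m_full > m_half > 1.0

    def test_commutes_with_drug_block_multipliers(self, base, iso, cq):
        a = ph.apply_iso(ph.apply_drugs(base, [cq]), iso)
        b = ph.apply_drugs(ph.apply_iso(base, iso), [cq])
        for ch in a.scale:
            assert a.scale[ch] == pytest.approx(b.scale[ch], rel=1e-12)

    def test_disable_phosphorylation(self, base, iso):
        assert ph.disable_iso_phosphorylation(iso, set()).targets == iso.targets
        off = ph.disable_iso_phosphorylation(iso, {"IKs", "ICaL"})
        out = ph.apply_iso(base, off)
        assert out.scale.get("IKs", 1.0) == pytest.approx(1.0)
        assert out.dv_act_mV == base.dv_act_mV
        all_off = ph.disable_iso_phosphorylation(iso, set(iso.targets))
        out = ph.apply_iso(base, all_off)
        assert all(v == pytest.approx(1.0) for v in out.scale.values())
        with pytest.raises(ValueError, match="not in effect set"):
            ph.disable_iso_phosphorylation(iso, {"IKr"})

    def test_fraction_must_be_in_unit_interval(self, iso):
        with pytest.raises(ValueError):
            iso.with_fraction(1.5)


def test_packaged_tables_load_with_expected_structure(library, iso):
    assert set(library) == {"CQ", "AZM"}
    assert library["CQ"].concentration_uM == 5.0
    assert library["AZM"].concentration_uM == 20.0
    for spec in library.values():
        for ch, b in spec.block_table().items():
            assert 0.0 <= b < 1.0
    assert {"IKs", "ICaL"} <= set(iso.targets)
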