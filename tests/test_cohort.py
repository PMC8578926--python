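"""Virtual-population sampling, scaling and plausibility-filter tests."""

import numpy as np
import pandas as pd
import pytest

from elastnet import (
    BPSummary,
    ParameterDistributions,
    ReferenceBPTable,
    derive_scales,
    generate_cohort,
    plausibility_filter,
    sample_parameters,
)
from elastnet.cohort import PLAUSIBILITY_Z


def _summary_at(ref: ReferenceBPTable, site: str, offsets=None):
    """BPSummary with each quantity at its reference mean + offset*SD."""
    offsets = offsets or {}
    vals = {}
    for q in ("SBP", "DBP", "MAP", "PP"):
        mean, sd = ref.values[f"{site}_{q}"]
        vals[q] = mean + offsets.get(q, 0.0) * sd
    # keep the dataclass invariants coherent: recompute PP and clamp MAP
    vals["PP"] = vals["SBP"] - vals["DBP"]
    vals["MAP"] = min(max(vals["MAP"], vals["DBP"]), vals["SBP"])
    return BPSummary(site=site, **vals)


class TestSampleParameters:
    def test_marginal_moments_match_table(self):
        df = sample_parameters(10000, seed=3)
        d = ParameterDistributions()
        for name in ("E_es", "HR", "TPR"):
            mean, sd, lo, hi = d.params[name]
            se = 3.0 * sd / np.sqrt(10000)
            assert abs(df[name].mean() - mean) < se + 0.05 * sd  # truncation shift
            assert df[name].std() == pytest.approx(sd, rel=0.1)

    def test_truncation_bounds_respected(self):
        df = sample_parameters(5000, seed=4)
        d = ParameterDistributions()
        for name, (_, _, lo, hi) in d.params.items():
            assert df[name].min() >= lo and df[name].max() <= hi

    def test_degenerate_sd_collapses_to_means(self):
        d = ParameterDistributions()
        tight = d.with_overrides(
            **{k: (v[0], 1e-12, v[2], v[3]) for k, v in d.params.items()}
        )
        df = sample_parameters(20, tight, seed=5)
        for name, (mean, *_rest) in d.params.items():
            assert np.allclose(df[name], mean)

    def test_same_seed_is_bit_identical(self):
        a = sample_parameters(100, seed=11)
        b = sample_parameters(100, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_sd_validation(self):
        with pytest.raises(ValueError, match="SD"):
            ParameterDistributions().with_overrides(E_es=(2.3, -1.0, 0.3, 6.0))


class TestDeriveScales:
    def test_reference_subject_has_unit_scales(self):
        h, d, c = derive_scales({"height": 180.0, "diameter": 33.2, "distensibility": 5.86})
        assert (h, d, c) == pytest.approx((1.0, 1.0, 1.0))

    def test_proportionality(self):
        h, d, c = derive_scales({"height": 90.0, "diameter": 16.6, "distensibility": 11.72})
        assert (h, d, c) == pytest.approx((0.5, 0.5, 2.0))


class TestPlausibilityFilter:
    def setup_method(self):
        self.ref = ReferenceBPTable.default()

    def test_all_at_means_accepted(self):
        ok, reason = plausibility_filter(
            _summary_at(self.ref, "brachial"), _summary_at(self.ref, "aortic"), self.ref
        )
        assert ok and reason == ""

    def test_three_sd_outlier_rejected_with_named_reason(self):
        bad = _summary_at(self.ref, "brachial", {"SBP": 3.0})
        ok, reason = plausibility_filter(bad, _summary_at(self.ref, "aortic"), self.ref)
        assert not ok
        assert reason == "brachial_SBP"

    def test_boundary_is_inclusive(self):
        mean, sd = self.ref.values["brachial_SBP"]
        edge = _summary_at(self.ref, "brachial")
        edge = BPSummary(
            site="brachial",
            SBP=mean + PLAUSIBILITY_Z * sd,
            DBP=edge.DBP,
            MAP=edge.MAP,
            PP=mean + PLAUSIBILITY_Z * sd - edge.DBP,
        )
        ref = ReferenceBPTable(
            {**self.ref.values,
             "brachial_PP": (edge.PP, self.ref.values["brachial_PP"][1] * 5)}
        )
        ok, reason = plausibility_filter(edge, _summary_at(ref, "aortic"), ref)
        assert ok, reason


class TestGenerateCohort:
    def test_bookkeeping(self, small_cohort):
        c = small_cohort
        assert c.n_requested == 40
        assert 0 < c.n_accepted <= 40
        assert c.n_accepted == sum(s.accepted for s in c.subjects)
        for s in c.accepted:
            assert s.E_es_true == s.params["E_es"]
            assert s.brachial_wave is not None and s.aortic_wave is not None

    def test_accepted_satisfy_the_filter(self, small_cohort):
        ref = ReferenceBPTable.default()
        for s in small_cohort.accepted:
            ok, reason = plausibility_filter(s.brachial_summary, s.aortic_summary, ref)
            assert ok, reason

    def test_reproducible_given_seed(self, small_cohort):
        again = generate_cohort(40, seed=123)
        a = small_cohort.to_dataframe()
        b = again.to_dataframe()
        pd.testing.assert_frame_equal(a, b)

    def test_vacuous_filter_accepts_all_converged(self):
        ref = ReferenceBPTable(
            {q: (100.0, 1e9) for q in ReferenceBPTable.default().values}
        )
        c = generate_cohort(15, ref=ref, seed=77)
        df = c.to_dataframe()
        n_failed = (df.reject_reason.isin(
            ["non_converged", "diverged", "systole_exceeds_cycle", "e_es_below_e_ed"]
        )).sum()
        assert c.n_accepted == 15 - n_failed

    def test_accepted_population_statistics(self, medium_cohort):
        """Filtering keeps a physiological mid-range contractility band and
        narrows the elastance spread below the nominal sampling SD."""
        df = medium_cohort.to_dataframe()
        acc = df[df.accepted]
        assert len(acc) > 30
        assert 1.8 <= acc.E_es.mean() <= 3.0
        nominal_sd = 1.0  # sampling distribution of E_es
        assert acc.E_es.std() < nominal_sd
        # filtered hemodynamics stay inside the normative band by construction
        assert 80 <= acc.brachial_SBP.mean() <= 165

    def test_acceptance_fraction_in_plausible_band(self, medium_cohort):
        """The plausibility filter keeps a sizeable minority of draws —
        broadly consistent with an in silico acceptance rate near 37%,
        allowing a wide band for the reduced-order simulator."""
        rate = medium_cohort.n_accepted / medium_cohort.n_requested
        assert 0.125 <= rate <= 0.625

    def test_waveform_matrix_shapes(self, small_cohort):
        waves, periods = small_cohort.waveform_matrix("brachial")
        assert waves.shape == (small_cohort.n_accepted, 200)
        assert periods.shape == (small_cohort.n_accepted,)
        assert np.all(np.isfinite(waves))
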