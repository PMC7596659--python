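import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chipbiome import array_quant as aq
from chipbiome.containers import ArrayManifest, SpotTable
from chipbiome.exceptions import InputError, InsufficientDataError

from .conftest import make_instance
from .oracles import brute_force_quantify


def _signals(mean_cy5, ratios=None):
    """Signal frame with the given mean Cy5 values (and optional ratios)."""
    idx = [f"sp{i:02d}" for i in range(len(mean_cy5))]
    mean_cy5 = np.asarray(mean_cy5, dtype=float)
    ratio = np.asarray(ratios, dtype=float) if ratios is not None else mean_cy5 / 100.0
    return pd.DataFrame(
        {"mean_cy5": mean_cy5, "mean_cy3": 100.0, "ratio": ratio, "n_spots": 3},
        index=pd.Index(idx, name="species"),
    )


def _simple_instance(cy5_triplicate, cy3_triplicate):
    rows = [{"probe_id": "p0", "cy5": a, "cy3": b} for a, b in zip(cy5_triplicate, cy3_triplicate)]
    manifest = ArrayManifest(
        pd.DataFrame(
            [{"probe_id": "p0", "species": "spA", "genus": "g", "family": "f", "order": "o"}]
        ).set_index("probe_id")
    )
    return SpotTable(sample_id="s", data=pd.DataFrame(rows)), manifest


class TestAggregateSpots:
    def test_triplicate_means_and_ratio(self):
        spots, manifest = _simple_instance([100, 110, 120], [50, 50, 50])
        out = aq.aggregate_spots(spots, manifest)
        assert out.at["spA", "mean_cy5"] == pytest.approx(110.0)
        assert out.at["spA", "ratio"] == pytest.approx(2.2)

    def test_single_spot_species_uses_that_spot(self):
        spots, manifest = _simple_instance([77], [11])
        out = aq.aggregate_spots(spots, manifest)
        assert out.at["spA", "mean_cy5"] == 77
        assert out.at["spA", "ratio"] == pytest.approx(7.0)

    def test_spot_order_is_irrelevant(self):
        rng = np.random.default_rng(0)
        spots, manifest = make_instance(rng)
        shuffled = SpotTable(
            sample_id="s1",
            data=spots.data.sample(frac=1.0, random_state=1).reset_index(drop=True),
        )
        pd.testing.assert_frame_equal(
            aq.aggregate_spots(spots, manifest), aq.aggregate_spots(shuffled, manifest)
        )

    def test_zero_reference_channel_flags_ratio_undefined(self):
        spots, manifest = _simple_instance([100, 100, 100], [0, 0, 0])
        out = aq.aggregate_spots(spots, manifest)
        assert np.isnan(out.at["spA", "ratio"])

    def test_unmapped_probe_rejected(self):
        spots, manifest = _simple_instance([1, 2, 3], [1, 1, 1])
        spots.data.loc[0, "probe_id"] = "mystery"
        with pytest.raises(InputError):
            aq.aggregate_spots(spots, manifest)


class TestBackgroundAndBaseline:
    def test_lowest_30_percent_of_ten(self):
        assert aq.estimate_background(_signals(range(1, 11))) == pytest.approx(2.0)

    def test_constant_intensity(self):
        assert aq.estimate_background(_signals([7.0] * 6)) == pytest.approx(7.0)

    def test_four_species_uses_single_lowest(self):
        sig = _signals([5.0, 1.0, 9.0, 3.0])
        assert aq.estimate_background(sig) == pytest.approx(1.0)

    def test_too_few_species(self):
        with pytest.raises(InsufficientDataError):
            aq.estimate_background(_signals([1, 2, 3]))

    def test_baseline_lower_half_of_four(self):
        sig = _signals([10] * 4, ratios=[1, 2, 3, 4])
        assert aq.estimate_baseline_ratio(sig) == pytest.approx(1.5)

    def test_baseline_odd_count_floors(self):
        sig = _signals([10] * 5, ratios=[5, 1, 4, 2, 3])
        assert aq.estimate_baseline_ratio(sig) == pytest.approx(1.5)

    def test_baseline_constant_ratio(self):
        sig = _signals([10] * 6, ratios=[2.5] * 6)
        assert aq.estimate_baseline_ratio(sig) == pytest.approx(2.5)

    def test_baseline_needs_two_defined_ratios(self):
        sig = _signals([10, 10], ratios=[np.nan, 1.0])
        with pytest.raises(InsufficientDataError):
            aq.estimate_baseline_ratio(sig)


class TestDetection:
    def test_both_passes_required(self):
        sig = _signals([1100.0], ratios=[6.0])
        calls = aq.call_detection(sig, background=100.0, baseline_ratio=1.0)
        assert calls[0].positive

    def test_exact_fivefold_is_negative(self):
        sig = _signals([500.0], ratios=[10.0])
        (call,) = aq.call_detection(sig, background=100.0, baseline_ratio=1.0)
        assert not call.pass_intensity and call.pass_ratio and not call.positive

    def test_ratio_at_baseline_blocks_positivity(self):
        sig = _signals([5000.0], ratios=[1.0])
        (call,) = aq.call_detection(sig, background=100.0, baseline_ratio=1.0)
        assert call.pass_intensity and not call.positive

    def test_undefined_ratio_is_negative(self):
        sig = _signals([5000.0], ratios=[np.nan])
        (call,) = aq.call_detection(sig, background=100.0, baseline_ratio=1.0)
        assert not call.positive


class TestNormalize:
    def test_ratio_share(self):
        sig = _signals([1000.0, 1000.0], ratios=[3.0, 1.0])
        calls = aq.call_detection(sig, background=10.0, baseline_ratio=0.1)
        ab = aq.normalize_abundance(calls, sig)
        assert ab.tolist() == pytest.approx([0.75, 0.25])

    def test_single_positive_gets_everything(self):
        sig = _signals([1000.0, 10.0], ratios=[3.0, 0.1])
        calls = aq.call_detection(sig, background=10.0, baseline_ratio=0.1)
        ab = aq.normalize_abundance(calls, sig)
        assert ab.tolist() == pytest.approx([1.0, 0.0])

    def test_no_positive_species_yields_zero_row(self):
        sig = _signals([10.0, 20.0], ratios=[0.1, 0.2])
        calls = aq.call_detection(sig, background=100.0, baseline_ratio=10.0)
        assert aq.normalize_abundance(calls, sig).sum() == 0.0


class TestCohort:
    def test_duplicate_sample_ids_rejected(self):
        rng = np.random.default_rng(1)
        spots, manifest = make_instance(rng)
        with pytest.raises(InputError):
            aq.quantify_cohort([spots, spots], manifest)

    def test_sample_order_permutes_rows_only(self, small_cohort):
        tables = small_cohort.spot_tables[:6]
        m1 = aq.quantify_cohort(tables, small_cohort.manifest)
        m2 = aq.quantify_cohort(tables[::-1], small_cohort.manifest)
        pd.testing.assert_frame_equal(m1.abundance, m2.abundance.loc[m1.abundance.index])

    def test_infinite_fold_blanks_everything(self, small_cohort):
        m = aq.quantify_cohort(
            small_cohort.spot_tables[:3], small_cohort.manifest, fold=np.inf
        )
        assert (m.abundance.to_numpy() == 0).all()
        assert not m.detected.to_numpy().any()

    @given(st.floats(min_value=0.01, max_value=100.0), st.integers(0, 10_000))
    def test_scale_invariance(self, c, seed):
        """Rescaling both channels of every spot leaves calls and abundances
        unchanged: the chain only depends on intensity ratios to per-array
        statistics."""
        rng = np.random.default_rng(seed)
        spots, manifest = make_instance(rng)
        scaled = SpotTable(
            sample_id="s1", data=spots.data.assign(cy5=spots.data.cy5 * c, cy3=spots.data.cy3 * c)
        )
        a1, r1 = aq.quantify_sample(spots, manifest)
        a2, r2 = aq.quantify_sample(scaled, manifest)
        pd.testing.assert_series_equal(a1, a2, rtol=1e-9)
        pd.testing.assert_series_equal(r1["positive"], r2["positive"])

    @given(st.integers(0, 10_000))
    def test_raising_own_cy5_never_loses_positivity(self, seed):
        rng = np.random.default_rng(seed)
        spots, manifest = make_instance(rng)
        _, report = aq.quantify_sample(spots, manifest)
        positive = report.index[report["positive"]]
        if len(positive) == 0:
            return
        target = positive[0]
        probes = manifest.data.index[manifest.data["species"] == target]
        boosted = spots.data.copy()
        sel = boosted["probe_id"].isin(probes)
        boosted.loc[sel, "cy5"] *= 3.0
        _, report2 = aq.quantify_sample(SpotTable("s1", boosted), manifest)
        assert report2.at[target, "positive"]


class TestRankAggregation:
    def test_additivity_and_conservation(self, small_cohort, small_matrix):
        genus = aq.aggregate_to_rank(small_matrix, small_cohort.manifest, "genus")
        mapping = small_cohort.manifest.rank_of("genus")
        g0 = genus.abundance.columns[0]
        members = mapping.index[mapping == g0]
        np.testing.assert_allclose(
            genus.abundance[g0], small_matrix.abundance[members].sum(axis=1)
        )
        np.testing.assert_allclose(
            genus.abundance.sum(axis=1), small_matrix.abundance.sum(axis=1)
        )

    def test_species_aggregation_is_identity(self, small_cohort, small_matrix):
        same = aq.aggregate_to_rank(small_matrix, small_cohort.manifest, "species")
        pd.testing.assert_frame_equal(same.abundance, small_matrix.abundance)

    def test_unknown_rank_rejected(self, small_cohort, small_matrix):
        with pytest.raises(InputError):
            aq.aggregate_to_rank(small_matrix, small_cohort.manifest, "phylum")


def test_chain_matches_brute_force_oracle():
    """Spot check of full-chain equivalence with the independent
    transcription (the acceptance suite runs 200 instances)."""
    rng = np.random.default_rng(99)
    for _ in range(25):
        spots, manifest = make_instance(rng)
        probe_map = manifest.data["species"].to_dict()
        rows = list(spots.data[["probe_id", "cy5", "cy3"]].itertuples(index=False, name=None))
        bg, bl, calls, ab = brute_force_quantify(rows, probe_map)
        signals = aq.aggregate_spots(spots, manifest)
        assert aq.estimate_background(signals) == pytest.approx(bg, abs=1e-12)
        assert aq.estimate_baseline_ratio(signals) == pytest.approx(bl, abs=1e-12)
        abundance, report = aq.quantify_sample(spots, manifest)
        for sp in ab:
            assert report.at[sp, "positive"] == calls[sp][2]
            assert abundance[sp] == pytest.approx(ab[sp], abs=1e-12)
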