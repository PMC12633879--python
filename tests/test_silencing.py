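"""Spike-slope normalization and the silencing-defect selection rule."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from ribopause import simulate
from ribopause.silencing import (
    ANEUPLOID_VS_EUPLOID,
    EUPLOID_REPRESSION,
    NormalizationError,
    apply_factors,
    builtin_contrast_test,
    call_silencing_defect,
    spike_slope_factors,
)


def _counts(ref, other, spikes=None):
    idx = [f"s{i}" for i in range(len(ref))]
    return pd.DataFrame({"A": ref, "B": other}, index=idx), (
        idx if spikes is None else spikes
    )


class TestSpikeSlope:
    @pytest.mark.parametrize("method", ["log", "lad", "ols"])
    def test_exact_doubling_gives_half_factor(self, method):
        ref = np.array([10.0, 20, 40, 80, 160, 320])
        counts, spikes = _counts(ref, 2 * ref)
        norm = spike_slope_factors(counts, spikes, "A", method=method)
        assert norm.factors["A"] == 1.0
        assert norm.factors["B"] == pytest.approx(0.5)
        assert norm.diagnostics.set_index("sample").loc["B", "slope"] == pytest.approx(2.0)

    def test_reference_vs_itself_is_one(self):
        ref = np.array([5.0, 9, 13, 80, 100])
        counts, spikes = _counts(ref, ref)
        norm = spike_slope_factors(counts, spikes, "A")
        assert norm.factors["B"] == pytest.approx(1.0)

    def test_too_few_spikes_rejected(self):
        counts, spikes = _counts(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
        with pytest.raises(NormalizationError):
            spike_slope_factors(counts, spikes, "A")

    def test_apply_factors_scales_column_sums_exactly(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(50, 3)).astype(float), columns=list("ABC")
        )
        factors = pd.Series({"A": 1.0, "B": 0.25, "C": 4.0})
        out = apply_factors(counts, factors)
        np.testing.assert_allclose(out.sum(), counts.sum() * factors)

    def test_normalization_idempotent(self):
        sim = simulate.simulate_spikein(simulate.SpikeConfig(), seed=5)
        norm = spike_slope_factors(sim.counts, sim.spike_genes, sim.reference_sample)
        refit = spike_slope_factors(
            apply_factors(sim.counts, norm), sim.spike_genes, sim.reference_sample
        )
        assert np.allclose(refit.diagnostics["slope"], 1.0, atol=1e-6)
        assert np.allclose(refit.factors, 1.0, atol=1e-6)

    def test_factor_recovery_on_simulated_spikes(self):
        sim = simulate.simulate_spikein(simulate.SpikeConfig(), seed=6)
        norm = spike_slope_factors(sim.counts, sim.spike_genes, sim.reference_sample)
        truth = pd.Series(sim.truth.spike_factors)
        # normalization factor is the reciprocal of the data-scale factor
        err = (norm.factors * truth - 1).abs()
        assert err.median() < 0.02
        assert err.max() < 0.06


def _stats_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "kind", "strain", "timepoint", "log2fc", "p_value", "fdr"],
    )


class TestSelectionRule:
    def _stats(self, repressed_fdr, aneu_patterns, gene="g"):
        rows = [
            (gene, EUPLOID_REPRESSION, "euploid", "d1", -2.0, 1e-4, repressed_fdr)
        ]
        for strain, (log2fc, fdr) in aneu_patterns.items():
            rows.append((gene, ANEUPLOID_VS_EUPLOID, strain, "d1", log2fc, 1e-4, fdr))
        return _stats_frame(rows)

    def test_three_of_four_aneuploids_excluded(self):
        patterns = {f"an{i}": (2.0, 0.01) for i in range(1, 4)}
        patterns["an4"] = (2.0, 0.5)  # not significant
        stats = self._stats(0.01, patterns)
        assert call_silencing_defect(stats) == []

    def test_all_four_aneuploids_selected(self):
        patterns = {f"an{i}": (2.0, 0.01) for i in range(1, 5)}
        stats = self._stats(0.01, patterns)
        assert call_silencing_defect(stats) == ["g"]

    def test_not_repressed_in_euploid_excluded(self):
        patterns = {f"an{i}": (2.0, 0.01) for i in range(1, 5)}
        stats = self._stats(0.8, patterns)
        assert call_silencing_defect(stats) == []

    def test_missing_aneuploid_contrast_raises_by_name(self):
        patterns = {f"an{i}": (2.0, 0.01) for i in range(1, 4)}
        stats = self._stats(0.01, patterns)
        with pytest.raises(ValueError, match="an4"):
            call_silencing_defect(stats, aneuploids=["an1", "an2", "an3", "an4"])

    def test_exhaustive_truth_table_four_aneuploids(self):
        """Every combination of per-strain significance patterns must agree
        with the plain boolean statement of the rule."""
        levels = [(-2.0, 0.01), (2.0, 0.01), (2.0, 0.5)]  # down-sig, up-sig, ns
        for rep_state in levels:
            for combo in product(range(3), repeat=4):
                patterns = {f"an{i+1}": levels[c] for i, c in enumerate(combo)}
                rows = [
                    ("g", EUPLOID_REPRESSION, "euploid", "d1", *[rep_state[0]], 1e-4, rep_state[1])
                ]
                for strain, (fc, fdr) in patterns.items():
                    rows.append(("g", ANEUPLOID_VS_EUPLOID, strain, "d1", fc, 1e-4, fdr))
                stats = _stats_frame(rows)
                selected = call_silencing_defect(stats)
                expected = (
                    rep_state[0] < 0
                    and rep_state[1] < 0.05
                    and all(fc > 0 and fdr < 0.05 for fc, fdr in patterns.values())
                )
                assert selected == (["g"] if expected else [])

    def test_removing_an_aneuploid_cannot_grow_the_set(self):
        rng = np.random.default_rng(7)
        rows = []
        genes = [f"g{i}" for i in range(50)]
        for g in genes:
            rows.append((g, EUPLOID_REPRESSION, "euploid", "d1",
                         rng.normal(-1), 1e-3, rng.uniform(0, 0.1)))
            for s in ("an1", "an2", "an3"):
                rows.append((g, ANEUPLOID_VS_EUPLOID, s, "d1",
                             rng.normal(1), 1e-3, rng.uniform(0, 0.1)))
        stats = _stats_frame(rows)
        full = set(call_silencing_defect(stats, aneuploids=["an1", "an2", "an3"]))
        fewer = set(call_silencing_defect(stats, aneuploids=["an1", "an2"]))
        assert full <= fewer  # dropping a requirement can only grow, never shrink
        # and permutation invariance to gene order
        shuffled = stats.sample(frac=1.0, random_state=1)
        assert set(call_silencing_defect(shuffled, aneuploids=["an1", "an2", "an3"])) == full


class TestBuiltinEngine:
    def test_null_significant_fraction_controlled(self):
        rng = np.random.default_rng(8)
        samples = {
            f"euploid_log_rep{r}": rng.lognormal(5, 0.2, 1000) for r in (1, 2)
        }
        samples |= {f"euploid_d1_rep{r}": rng.lognormal(5, 0.2, 1000) for r in (1, 2)}
        samples |= {f"an1_d1_rep{r}": rng.lognormal(5, 0.2, 1000) for r in (1, 2)}
        counts = pd.DataFrame(samples, index=[f"g{i}" for i in range(1000)])
        sheet = pd.DataFrame(
            [
                (s, s.split("_")[0] if not s.startswith("euploid") else "euploid",
                 s.split("_")[1], int(s[-1]))
                for s in counts.columns
            ],
            columns=["sample", "strain", "timepoint", "replicate"],
        )
        stats = builtin_contrast_test(counts, sheet)
        for _, grp in stats.groupby(["kind", "strain", "timepoint"]):
            assert (grp["fdr"] < 0.05).mean() <= 0.10

    def test_planted_eightfold_changes_detected(self):
        rng = np.random.default_rng(9)
        base = rng.lognormal(6, 0.5, 500)
        changed = np.zeros(500, dtype=bool)
        changed[:50] = True
        cv = 0.2
        sigma = np.sqrt(np.log1p(cv**2))

        def draw(mult):
            return base * mult * rng.lognormal(0, sigma, 500)

        counts = pd.DataFrame(
            {
                "euploid_log_rep1": draw(1),
                "euploid_log_rep2": draw(1),
                "euploid_d1_rep1": draw(1),
                "euploid_d1_rep2": draw(1),
                "an1_d1_rep1": draw(np.where(changed, 8.0, 1.0)),
                "an1_d1_rep2": draw(np.where(changed, 8.0, 1.0)),
            },
            index=[f"g{i}" for i in range(500)],
        )
        sheet = pd.DataFrame(
            [
                ("euploid_log_rep1", "euploid", "log", 1),
                ("euploid_log_rep2", "euploid", "log", 2),
                ("euploid_d1_rep1", "euploid", "d1", 1),
                ("euploid_d1_rep2", "euploid", "d1", 2),
                ("an1_d1_rep1", "an1", "d1", 1),
                ("an1_d1_rep2", "an1", "d1", 2),
            ],
            columns=["sample", "strain", "timepoint", "replicate"],
        )
        stats = builtin_contrast_test(counts, sheet)
        aneu = stats[(stats["kind"] == ANEUPLOID_VS_EUPLOID)].set_index("gene_id")
        hits = aneu[(aneu["fdr"] < 0.05) & (aneu["log2fc"] > 0)].index
        power = np.isin([f"g{i}" for i in range(50)], hits).mean()
        assert power >= 0.9

    def test_round_trips_through_selection_rule(self):
        sim = simulate.simulate_spikein(
            simulate.SpikeConfig(n_genes=300, n_repressed_genes=80, n_defect_genes=30),
            seed=10,
        )
        norm = spike_slope_factors(sim.counts, sim.spike_genes, sim.reference_sample)
        normalized = apply_factors(sim.counts, norm, drop_genes=sim.spike_genes)
        stats = builtin_contrast_test(normalized, sim.sample_sheet)
        selected = call_silencing_defect(stats)
        truth = set(sim.truth.silencing_defect_genes)
        assert truth == set(selected)
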