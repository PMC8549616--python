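import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multistress import mechanisms, synthdata
from multistress.dataio import ValidationError
from multistress.mechanisms import (
    HISTORICAL_TRANSITIONS,
    TransitionSpec,
    decompose_transition,
    run_historical_transitions,
)
from multistress.synthdata import SyntheticConfig, WeibullHazard

from conftest import make_records

T1 = TransitionSpec("T1", "EP", "PP", "HALI", "HAHI")


def records_from_cell_means(means, n_genotypes=2, n_reps=2, jitter=0.0, seed=0):
    """Exact-cell-mean records: every animal in a cell carries the cell mean
    (optionally jittered symmetrically so means are preserved exactly)."""
    rng = np.random.default_rng(seed)
    cells = []
    for (pop, arm), mean in means.items():
        for g in range(1, n_genotypes + 1):
            vals = []
            for _ in range(n_reps):
                eps = rng.normal(0, jitter) if jitter else 0.0
                vals.append({"fecundity": mean + eps, "size_mm": 1.0, "age_days": 1.0})
                vals.append({"fecundity": mean - eps, "size_mm": 1.0, "age_days": 1.0})
            cells.append((pop, arm, f"{pop}-g{g}", vals))
    return make_records(cells)


class TestDecomposeTransition:
    def test_hand_arithmetic_example(self):
        means = {("EP", "HALI"): 10.0, ("EP", "HAHI"): 8.0,
                 ("PP", "HALI"): 12.0, ("PP", "HAHI"): 12.0}
        res = decompose_transition(
            records_from_cell_means(means), T1, "fecundity", fit_tests=False
        )
        assert res.plasticity == pytest.approx(-2.0, abs=1e-12)
        assert res.genetic_evolution == pytest.approx(2.0, abs=1e-12)
        assert res.evolution_of_plasticity == pytest.approx(2.0, abs=1e-12)
        for pct in res.relative_contribution.values():
            assert pct == pytest.approx(100 / 3, abs=1e-9)

    def test_all_cells_equal_gives_zero_and_nan_contributions(self):
        means = {("EP", "HALI"): 5.0, ("EP", "HAHI"): 5.0,
                 ("PP", "HALI"): 5.0, ("PP", "HAHI"): 5.0}
        res = decompose_transition(
            records_from_cell_means(means), T1, "fecundity", fit_tests=False
        )
        assert res.plasticity == 0 and res.genetic_evolution == 0
        assert res.evolution_of_plasticity == 0
        assert all(np.isnan(v) for v in res.relative_contribution.values())

    def test_empty_cell_errors(self):
        means = {("EP", "HALI"): 10.0, ("EP", "HAHI"): 8.0, ("PP", "HALI"): 12.0}
        with pytest.raises(ValidationError, match="empty cell"):
            decompose_transition(
                records_from_cell_means(means), T1, "fecundity", fit_tests=False
            )

    @given(st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=4, max_size=4
    ))
    @settings(max_examples=50, deadline=None)
    def test_reconstruction_identity(self, m):
        means = {("EP", "HALI"): m[0], ("EP", "HAHI"): m[1],
                 ("PP", "HALI"): m[2], ("PP", "HAHI"): m[3]}
        res = decompose_transition(
            records_from_cell_means(means), T1, "fecundity", fit_tests=False
        )
        lhs = m[3]
        rhs = m[0] + res.plasticity + res.genetic_evolution + res.evolution_of_plasticity
        assert lhs == pytest.approx(rhs, abs=1e-12 * max(1.0, abs(lhs)))

    def test_double_coding_swap_preserves_gxe_magnitude(self):
        means = {("EP", "HALI"): 10.0, ("EP", "HAHI"): 7.5,
                 ("PP", "HALI"): 13.0, ("PP", "HAHI"): 11.0}
        fwd = decompose_transition(
            records_from_cell_means(means), T1, "fecundity", fit_tests=False
        )
        swapped = TransitionSpec("T1r", "PP", "EP", "HAHI", "HALI")
        rev = decompose_transition(
            records_from_cell_means(means), swapped, "fecundity", fit_tests=False
        )
        assert abs(rev.evolution_of_plasticity) == pytest.approx(
            abs(fwd.evolution_of_plasticity), abs=1e-12
        )

    def test_double_coding_swap_flips_signs_when_gxe_zero(self):
        # with zero interaction the swap exactly negates both main components
        means = {("EP", "HALI"): 10.0, ("EP", "HAHI"): 8.0,
                 ("PP", "HALI"): 13.0, ("PP", "HAHI"): 11.0}
        fwd = decompose_transition(
            records_from_cell_means(means), T1, "fecundity", fit_tests=False
        )
        assert fwd.evolution_of_plasticity == pytest.approx(0.0, abs=1e-12)
        swapped = TransitionSpec("T1r", "PP", "EP", "HAHI", "HALI")
        rev = decompose_transition(
            records_from_cell_means(means), swapped, "fecundity", fit_tests=False
        )
        assert rev.plasticity == pytest.approx(-fwd.plasticity, abs=1e-12)
        assert rev.genetic_evolution == pytest.approx(-fwd.genetic_evolution, abs=1e-12)

    def test_relative_contribution_scale_invariant(self):
        means = {("EP", "HALI"): 10.0, ("EP", "HAHI"): 7.0,
                 ("PP", "HALI"): 12.0, ("PP", "HAHI"): 12.5}
        base = decompose_transition(
            records_from_cell_means(means), T1, "fecundity", fit_tests=False
        )
        scaled_means = {k: 7.3 * v for k, v in means.items()}
        scaled = decompose_transition(
            records_from_cell_means(scaled_means), T1, "fecundity", fit_tests=False
        )
        for comp in base.relative_contribution:
            assert scaled.relative_contribution[comp] == pytest.approx(
                base.relative_contribution[comp], abs=1e-9
            )

    def test_contrast_tests_detect_configured_effects(self):
        cfg = SyntheticConfig(
            populations=("EP", "PP"), arms=("HALI", "HAHI"),
            population_effects={"PP": {"fecundity": 2.0}},
            treatment_effects={"HAHI": {"fecundity": -2.0}},
            sd_genotype=0.1, sd_batch=0.0, sd_residual=0.5,
            hazard=WeibullHazard(scale=1e6), seed=77, n_replicates=10,
        )
        records, _ = synthdata.generate_experiment(cfg)
        res = decompose_transition(records, T1, "fecundity", fit_tests=True)
        tests = res.contrast_tests.set_index("component")
        assert tests.loc["plasticity", "p"] < 0.001
        assert tests.loc["genetic_evolution", "p"] < 0.001
        assert tests.loc["evolution_of_plasticity", "p"] > 0.01

    def test_recovery_against_configured_truth(self):
        # truth: plasticity -2, genetic +2, GxE +2 via a pop x arm shift
        cfg = SyntheticConfig(
            populations=("EP", "PP"), arms=("HALI", "HAHI"),
            population_effects={"PP": {"fecundity": 2.0}},
            treatment_effects={"HAHI": {"fecundity": -2.0}},
            pop_arm_effects={("PP", "HAHI"): {"fecundity": 2.0}},
            sd_genotype=0.05, sd_batch=0.0, sd_residual=0.1,
            hazard=WeibullHazard(scale=1e6), seed=101, n_replicates=10,
        )
        ests = []
        for rep in range(30):
            records, _ = synthdata.generate_experiment(cfg, seed=1000 + rep)
            res = decompose_transition(records, T1, "fecundity", fit_tests=False)
            ests.append([res.plasticity, res.genetic_evolution,
                         res.evolution_of_plasticity])
        ests = np.array(ests)
        mc_se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        truth = np.array([-2.0, 2.0, 2.0])
        assert (np.abs(ests.mean(axis=0) - truth) < 3 * np.maximum(mc_se, 1e-9)).all()


class TestTransitionSpec:
    def test_degenerate_cells_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            TransitionSpec("bad", "EP", "EP", "HALI", "HALI")

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError, match="unknown arm"):
            TransitionSpec("bad", "EP", "PP", "HALI", "XX")

    def test_historical_set(self):
        assert len(HISTORICAL_TRANSITIONS) == 5
        labels = {t.label for t in HISTORICAL_TRANSITIONS}
        assert "T1_T2_multistress" in labels and "T2_T3_algae" in labels


class TestRunHistoricalTransitions:
    def test_full_grid_shape(self, demo_records):
        out = run_historical_transitions(demo_records, fit_tests=False)
        # 5 transitions x 3 traits x 3 components
        assert len(out) == 45
        assert set(out["component"]) == set(mechanisms.COMPONENTS)

    def test_pure_plasticity_attribution(self):
        cfg = SyntheticConfig(
            treatment_effects=synthdata.additive_treatment_effects({
                "HA": {"fecundity": 1.0}, "LA": {"fecundity": -3.0},
                "HI": {"fecundity": -2.0}, "LI": {"fecundity": -1.0},
            }),
            sd_genotype=0.05, sd_batch=0.0, sd_residual=0.1,
            hazard=WeibullHazard(scale=1e6), seed=55, n_replicates=5,
        )
        records, _ = synthdata.generate_experiment(cfg)
        out = run_historical_transitions(records, fit_tests=False)
        sub = out.query("transition=='T2_T3_algae' and trait=='fecundity'")
        rel = dict(zip(sub["component"], sub["rel_contribution_pct"]))
        assert rel["plasticity"] > 90

    def test_pure_genetic_attribution(self):
        cfg = SyntheticConfig(
            population_effects={"PP": {"fecundity": 3.0}, "CWP": {"fecundity": -1.0}},
            sd_genotype=0.05, sd_batch=0.0, sd_residual=0.1,
            hazard=WeibullHazard(scale=1e6), seed=56, n_replicates=5,
        )
        records, _ = synthdata.generate_experiment(cfg)
        out = run_historical_transitions(records, fit_tests=False)
        for label in ("T1_T2_multistress", "T2_T3_multistress"):
            sub = out.query("transition==@label and trait=='fecundity'")
            rel = dict(zip(sub["component"], sub["rel_contribution_pct"]))
            assert rel["genetic_evolution"] > 90

    def test_missing_arm_skips_transition(self, demo_config):
        cfg_dict = {
            "arms": ("CTRL", "HALI", "HAHI"),
            "seed": 5, "n_replicates": 3,
            "hazard": WeibullHazard(scale=1e6),
        }
        records, _ = synthdata.generate_experiment(SyntheticConfig(**cfg_dict))
        out = run_historical_transitions(records, fit_tests=False)
        assert set(out["transition"]) == {"T1_T2_multistress"}

    def test_output_columns(self, demo_records):
        out = run_historical_transitions(
            demo_records, traits=("fecundity",),
            transitions=HISTORICAL_TRANSITIONS[:1], fit_tests=True,
        )
        assert list(out.columns) == [
            "transition", "trait", "component", "estimate",
            "rel_contribution_pct", "chisq", "df", "p",
        ]
        assert out["p"].notna().all()
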