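"""End-to-end runs, figure data contracts, family-effect flagging."""

import numpy as np
import pytest

import psfsignal as ps
from psfsignal.hier_models import ModelSpec, PosteriorResult, build_model
from psfsignal.report import (
    plot_dissimilarity,
    plot_family_effects,
    plot_model_fit_density,
    run_analysis,
)


def _sim_config(n_pairs=60, seed=11, model_id=5, **extra):
    return {
        "simulation": dict(
            n_pairs=n_pairs, n_species=40, n_families=8, seed=seed,
            generating_model_id=model_id, **extra,
        ),
        "seed": seed,
    }


@pytest.fixture(scope="module")
def smoke_report(tmp_path_factory):
    """One full run: simulate 60 pairs, fit all seven models."""
    out = tmp_path_factory.mktemp("smoke")
    config = _sim_config() | dict(chains=2, iterations=2000, burn_in=400)
    return run_analysis(config, output_dir=out), out


def test_smoke_run_emits_seven_row_loo_table(smoke_report):
    report, out = smoke_report
    assert len(report.loo_table.table) == 7
    assert report.failures == {}
    assert (out / "loo_table.csv").exists()
    assert (out / "run_log.json").exists()
    assert (out / "family_effects.csv").exists()
    # every fitted model appears exactly once
    assert sorted(report.loo_table.table["model"]) == list(range(1, 8))


def test_smoke_run_delta_consistent_with_loo(smoke_report):
    report, _ = smoke_report
    table = report.loo_table.table
    np.testing.assert_allclose(
        table["delta_loo"], table["loo"] - table["loo"].min(), atol=1e-12
    )


def test_restricted_model_set_gives_two_rows(tmp_path):
    config = _sim_config() | dict(models=[1, 2], chains=2, iterations=300, burn_in=100)
    report = run_analysis(config, output_dir=tmp_path)
    assert list(sorted(report.loo_table.table["model"])) == [1, 2]


def test_rerun_with_same_seed_is_byte_identical(tmp_path):
    config = _sim_config() | dict(models=[1, 2, 5], chains=2, iterations=400, burn_in=150)
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    run_analysis(config, output_dir=out_a)
    run_analysis(config, output_dir=out_b)
    for name in ("loo_table.csv", "model1_summary.csv", "model5_summary.csv",
                 "dissimilarity_vs_distance.csv"):
        assert (out_a / name).read_bytes() == (out_b / name).read_bytes(), name


def test_dissimilarity_plot_counts(small_pairs):
    fig, frame = plot_dissimilarity(small_pairs)
    n_obs = sum(p.n_replicates for p in small_pairs)
    assert (frame["kind"] == "replicate").sum() == n_obs
    assert (frame["kind"] == "pair_mean").sum() == len(small_pairs)


def test_dissimilarity_plot_single_pair():
    pair = ps.SpeciesPair(
        pair_id="x__y", species_a_id="x", species_b_id="y",
        family_a="F1", family_b="F2", t_myr=100.0,
        observations=[ps.DissimilarityObservation(0.4, 0.01, "x__y")],
    )
    _, frame = plot_dissimilarity([pair])
    assert (frame["kind"] == "pair_mean").sum() == 1


def test_density_plot_bins_and_overlays(small_pairs):
    fits = {
        "normal": (ModelSpec(4), {"beta": 0.0, "sigma": 0.5, "k": 0.05}),
        "student_t": (ModelSpec(6), {"beta": 0.0, "s": 0.4, "upsilon": 3.0, "k": -0.1}),
    }
    _, export = plot_model_fit_density(small_pairs, fits)
    assert set(export) <= {"within", "between"}
    for label, bin_data in export.items():
        assert bin_data["n"] > 0
        boundary = 300.0
        assert (bin_data["median_t_myr"] <= boundary) == (label == "within")
    # heavy-tailed overlay peaks above the matched normal at the centre
    between = export["between"]
    grid = np.asarray(between["grid"])
    centre = np.argmin(np.abs(grid))
    assert between["overlays"]["student_t"][centre] > between["overlays"]["normal"][centre]


def test_density_plot_single_value_bin():
    pair = ps.SpeciesPair(
        pair_id="x__y", species_a_id="x", species_b_id="y",
        family_a="F1", family_b="F1", t_myr=100.0,
        observations=[ps.DissimilarityObservation(0.4, 0.01, "x__y")],
    )
    _, export = plot_model_fit_density(
        [pair], {"normal": (ModelSpec(1), {"sigma": 0.5})}
    )
    assert export["within"]["variance"] == 0.0
    assert "between" not in export  # empty bin omitted


def _alpha_result(alpha_centre, family_pairs, n=400):
    rng = np.random.default_rng(0)
    alpha = rng.normal(alpha_centre, 0.05, size=(2, n, len(family_pairs)))
    return PosteriorResult(
        spec=ModelSpec(7),
        draws={"alpha": alpha},
        pointwise_loglik=np.zeros((2, n, 3)),
        rhat={}, seed=0, pair_ids=["p0", "p1", "p2"],
        family_pairs=family_pairs,
    )


def test_family_effects_flagging_logic(tiny_pairs):
    fams = sorted({p.family_pair_id for p in tiny_pairs})
    centre = np.zeros(len(fams))
    _, frame = plot_family_effects(_alpha_result(centre, fams), tiny_pairs)
    assert not frame["significant"].any()
    centre[0] = 1.5
    _, frame = plot_family_effects(_alpha_result(centre, fams), tiny_pairs)
    flagged = frame[frame["significant"]]
    assert list(flagged["family_pair"]) == [fams[0]]


def test_injected_family_shift_detected():
    """A 1.5-unit family-pair deviation survives fitting and gets flagged."""
    params = ps.default_true_params(7) | {"s_alpha": 0.1, "k": -0.1}
    cfg = ps.SimulationConfig(
        n_pairs=120, n_species=60, n_families=6, seed=23,
        generating_model=ModelSpec(7, params=params),
    )
    table, truth = ps.simulate_pairs(cfg)
    pairs = ps.assemble_pairs(ps.filter_whole_soil(table))
    # inject a strong shift into the best-sampled family pair
    counts = {}
    for p in pairs:
        counts[p.family_pair_id] = counts.get(p.family_pair_id, 0) + p.n_replicates
    target = max(counts, key=counts.get)
    for p in pairs:
        if p.family_pair_id == target:
            p.observations = [
                ps.DissimilarityObservation(o.r + 1.5, o.var_r, o.pair_id, o.replicate_index)
                for o in p.observations
            ]
    res = ps.fit(build_model(7, pairs), chains=2, iterations=1500, burn_in=500, seed=3)
    _, frame = plot_family_effects(res, pairs)
    row = frame[frame["family_pair"] == target].iloc[0]
    assert row["significant"]
    assert row["alpha_mean"] > 0.5
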