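"""Synthetic landrace-DH and breeding-line study generator.

The generator emulates the structure the pipeline is built for: a few
self-contained landrace populations, each sampled as doubled-haploid (DH)
lines that are recombinant mosaics of a small founder set, plus a breeding
panel assembled from an overlapping founder subset so that part of the
landrace haplotype space is absent from the breeding lines. Window-haplotype
QTLs with stable, environment-interacting or null effect patterns are
planted on top of a kinship-structured polygenic background and
environment-specific residual noise.

No generative model is published for the real material; every
distributional choice here is a documented stand-in (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .lmm import compute_kinship
from .types import ACROSS_ENV, GenotypePanel, MarkerMap, PhenotypeTable
from .windows import build_windows, call_haplotypes

PATTERNS = ("stable+", "stable-", "interacting", "null")


@dataclass
class QTLSpec:
    """One planted window-haplotype QTL.

    ``hap_rank`` indexes the window's haplotypes by descending carrier count
    in the DH panel (0 = most frequent). Effects are on the 0/2 allele-coded
    scale, i.e. a carrier line differs from a non-carrier by 2*effect in
    expectation.
    """

    window: int
    hap_rank: int
    effect_size: float
    pattern: str  # stable+ / stable- / interacting / null
    effects: tuple[float, ...] | None = None  # explicit per-env effects override

    def per_env_effects(self, n_env: int) -> np.ndarray:
        if self.effects is not None:
            eff = np.asarray(self.effects, float)
            if len(eff) != n_env:
                raise ValueError("per-environment effect vector length mismatch")
            return eff
        b = float(self.effect_size)
        if self.pattern == "stable+":
            return np.full(n_env, b)
        if self.pattern == "stable-":
            return np.full(n_env, -b)
        if self.pattern == "interacting":
            half = n_env // 2
            return np.array([b] * (n_env - half) + [-b] * half)
        if self.pattern == "null":
            return np.zeros(n_env)
        raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass
class SimConfig:
    n_landraces: int = 3
    founders_per_landrace: int = 8
    dh_per_landrace: int = 200
    n_breeding: int = 64
    n_chromosomes: int = 3
    snps_per_chromosome: int = 400
    chrom_length_bp: int = 160_000_000
    chrom_length_cM: float = 160.0
    n_environments: int = 6
    qtl_spec: list[QTLSpec] = field(default_factory=list)
    polygenic_variance: float = 0.5
    residual_variance_per_env: tuple[float, ...] | float = 1.0
    env_means: tuple[float, ...] | float = 0.0
    landrace_means: tuple[float, ...] | float = 0.0
    seed: int = 0
    # ancestry knobs (stand-ins; see docs/methods.md)
    ancestral_pool_size: int = 16
    breeding_founder_pool: int = 10
    private_mutation_rate: float = 0.01
    trait: str = "TRAIT"

    def __post_init__(self) -> None:
        for name in ("n_landraces", "founders_per_landrace", "dh_per_landrace",
                     "n_chromosomes", "snps_per_chromosome", "n_environments"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_breeding < 0:
            raise ValueError("n_breeding must be >= 0")
        if self.polygenic_variance < 0:
            raise ValueError("polygenic_variance must be >= 0")
        if np.any(np.asarray(self.residual_variances) < 0):
            raise ValueError("residual variances must be >= 0")
        if self.chrom_length_cM < 0:
            raise ValueError("chromosome cM length must be >= 0")

    @property
    def residual_variances(self) -> np.ndarray:
        v = self.residual_variance_per_env
        if np.isscalar(v):
            return np.full(self.n_environments, float(v))
        v = np.asarray(v, float)
        if len(v) != self.n_environments:
            raise ValueError("residual_variance_per_env length != n_environments")
        return v

    @property
    def env_mean_vector(self) -> np.ndarray:
        v = self.env_means
        if np.isscalar(v):
            return np.full(self.n_environments, float(v))
        return np.asarray(v, float)

    @property
    def landrace_mean_vector(self) -> np.ndarray:
        v = self.landrace_means
        if np.isscalar(v):
            return np.full(self.n_landraces, float(v))
        return np.asarray(v, float)

    @property
    def landrace_names(self) -> list[str]:
        return [f"LR{i + 1}" for i in range(self.n_landraces)]

    @property
    def environment_names(self) -> list[str]:
        return [f"ENV{i + 1}" for i in range(self.n_environments)]


@dataclass
class TruthTable:
    """Machine-readable ground truth for recovery tests."""

    qtls: pd.DataFrame  # window_id, hap_id, allele_string, pattern, carrier_count, effect_ENV*
    polygenic_values: pd.Series  # per line
    variance_components: dict

    def to_json(self, path) -> None:
        obj = {
            "qtls": self.qtls.to_dict(orient="records"),
            "polygenic_values": self.polygenic_values.to_dict(),
            "variance_components": self.variance_components,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


# ---------------------------------------------------------------------------
# Genotypes


def _meiosis(rng: np.random.Generator, hapA: np.ndarray, hapB: np.ndarray,
             pos_cm: np.ndarray, length_cm: float) -> np.ndarray:
    """One gamete from two parental haplotypes: Poisson(cM/100) crossovers,
    positions uniform on the genetic map, no interference."""
    n_x = rng.poisson(length_cm / 100.0)
    if n_x == 0:
        return (hapA if rng.random() < 0.5 else hapB).copy()
    if length_cm <= 0:
        raise ValueError("cannot place crossovers on a zero-length genetic map")
    cuts = np.sort(rng.uniform(0.0, length_cm, n_x))
    seg = np.searchsorted(cuts, pos_cm, side="right")
    start = int(rng.integers(2))
    take_a = (seg + start) % 2 == 0
    return np.where(take_a, hapA, hapB)


def _unique_positions(rng: np.random.Generator, length_bp: int, m: int) -> np.ndarray:
    """m distinct sorted 1-based bp positions without materializing the genome."""
    if m > length_bp:
        raise ValueError("more SNPs requested than base pairs")
    draw = rng.integers(1, length_bp + 1, size=2 * m + 16)
    pos = np.unique(draw)
    while len(pos) < m:
        draw = rng.integers(1, length_bp + 1, size=2 * m)
        pos = np.unique(np.concatenate([pos, draw]))
    return np.sort(rng.choice(pos, size=m, replace=False))


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """DH libraries plus breeding panel as founder mosaics; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    m_per = config.snps_per_chromosome
    n_chrom = config.n_chromosomes

    # marker map: uniform sorted bp positions, linear cM
    map_rows = []
    for c in range(n_chrom):
        pos = _unique_positions(rng, config.chrom_length_bp, m_per)
        cm = pos / config.chrom_length_bp * config.chrom_length_cM
        for k in range(m_per):
            map_rows.append(
                {"marker": f"chr{c + 1}_snp{k + 1}", "chrom": f"chr{c + 1}",
                 "pos_bp": int(pos[k]), "pos_cM": float(cm[k])}
            )
    marker_map = MarkerMap(pd.DataFrame(map_rows))
    m = len(marker_map)

    # ancestral haplotype pool
    p_anc = rng.uniform(0.1, 0.9, m)
    pool = (rng.random((config.ancestral_pool_size, m)) < p_anc).astype(np.int8)

    # landrace founder sets: draw from the pool, add landrace-private mutations
    founders: dict[str, np.ndarray] = {}
    for j, lr in enumerate(config.landrace_names):
        pick = rng.choice(config.ancestral_pool_size, size=config.founders_per_landrace,
                          replace=config.founders_per_landrace > config.ancestral_pool_size)
        F = pool[pick].copy()
        flips = rng.random(F.shape) < config.private_mutation_rate
        F ^= flips.astype(np.int8)
        founders[lr] = F

    # breeding founder subset overlaps the ancestral pool
    n_bf = min(config.breeding_founder_pool, config.ancestral_pool_size)
    breeding_founders = pool[rng.choice(config.ancestral_pool_size, n_bf, replace=False)]

    chrom_slices = [slice(c * m_per, (c + 1) * m_per) for c in range(n_chrom)]
    pos_cm_all = marker_map.table["pos_cM"].to_numpy()

    def make_line(F: np.ndarray) -> np.ndarray:
        if F.shape[0] == 1:
            return F[0].copy()
        a, b = rng.choice(F.shape[0], 2, replace=False)
        out = np.empty(m, np.int8)
        for sl in chrom_slices:
            out[sl] = _meiosis(rng, F[a, sl], F[b, sl], pos_cm_all[sl],
                               config.chrom_length_cM)
        return out

    lines, pops, rows = [], [], []
    for lr in config.landrace_names:
        for i in range(config.dh_per_landrace):
            lines.append(f"{lr}_DH{i + 1:04d}")
            pops.append(lr)
            rows.append(make_line(founders[lr]))
    for i in range(config.n_breeding):
        lines.append(f"BL{i + 1:03d}")
        pops.append("breeding")
        rows.append(make_line(breeding_founders))

    geno = np.vstack(rows) * 2  # doubled gametes: homozygous 0/2
    return GenotypePanel(lines, pops, geno, marker_map)


# ---------------------------------------------------------------------------
# QTL planting


def plant_qtls(panel: GenotypePanel, config: SimConfig) -> TruthTable:
    """Resolve the configured QTLs against the generated haplotype catalog."""
    windows = build_windows(panel.marker_map, 10)
    dh = panel.subset_lines(np.array([p != "breeding" for p in panel.populations]))
    catalog, matrix = call_haplotypes(dh, windows)

    qtl_rows = []
    for q in config.qtl_spec:
        if q.pattern not in PATTERNS:
            raise ValueError(f"unknown QTL pattern {q.pattern!r}")
        sub = catalog.table[catalog.table["window_id"] == q.window]
        if sub.empty:
            raise ValueError(f"QTL window {q.window} not in genome")
        sub = sub.sort_values(["count_all", "allele_string"], ascending=[False, True])
        if q.hap_rank >= len(sub):
            raise ValueError(f"window {q.window} has only {len(sub)} haplotypes")
        rec = sub.iloc[q.hap_rank]
        if rec["count_all"] == 0:
            raise ValueError(f"planted haplotype in window {q.window} has zero carriers")
        eff = q.per_env_effects(config.n_environments)
        _check_pattern(q.pattern, eff)
        row = {
            "window_id": int(q.window),
            "hap_id": int(rec["hap_id"]),
            "allele_string": rec["allele_string"],
            "pattern": q.pattern,
            "carrier_count": int(rec["count_all"]),
            "carrier_freq": float(rec["freq_all"]),
        }
        for e, env in enumerate(config.environment_names):
            row[f"effect_{env}"] = float(eff[e])
        qtl_rows.append(row)

    cols = ["window_id", "hap_id", "allele_string", "pattern", "carrier_count",
            "carrier_freq"] + [f"effect_{e}" for e in config.environment_names]
    qtls = pd.DataFrame(qtl_rows, columns=cols)

    # polygenic values with covariance proportional to kinship, normalized so
    # the average line variance equals polygenic_variance
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7**5]))
    u = np.zeros(dh.n_lines)
    if config.polygenic_variance > 0:
        K = compute_kinship(dh.geno)
        K = K / np.mean(np.diag(K))
        w, V = np.linalg.eigh(K)
        w = np.clip(w, 0.0, None)
        u = V @ (np.sqrt(config.polygenic_variance * w) * rng.standard_normal(dh.n_lines))
    truth = TruthTable(
        qtls=qtls,
        polygenic_values=pd.Series(u, index=dh.lines),
        variance_components={
            "polygenic_variance": float(config.polygenic_variance),
            "residual_variance_per_env": config.residual_variances.tolist(),
        },
    )
    truth.matrix = matrix  # cached for phenotype simulation
    truth.windows = windows
    return truth


def _check_pattern(pattern: str, eff: np.ndarray) -> None:
    nz = eff[eff != 0]
    ok = {
        "stable+": len(nz) > 0 and np.all(nz > 0),
        "stable-": len(nz) > 0 and np.all(nz < 0),
        "interacting": np.any(nz > 0) and np.any(nz < 0),
        "null": len(nz) == 0,
    }[pattern]
    if not ok:
        raise ValueError(f"effects {eff} inconsistent with pattern {pattern!r}")


# ---------------------------------------------------------------------------
# Phenotypes


def simulate_phenotypes(
    panel: GenotypePanel, truth: TruthTable, config: SimConfig
) -> PhenotypeTable:
    """Per-environment values plus across-environment means as BLUE stand-ins.

    y_ik = env_mean_i + landrace_mean_j(k) + sum_q x_kq beta_q^i + u_k + e_ik
    with x in {0,2} and environment-specific residual variance.
    """
    dh_mask = np.array([p != "breeding" for p in panel.populations])
    dh = panel.subset_lines(dh_mask)
    if list(truth.polygenic_values.index) != dh.lines:
        raise ValueError("truth and panel line sets do not match")
    matrix = getattr(truth, "matrix", None)
    if matrix is None:
        windows = build_windows(panel.marker_map, 10)
        _, matrix = call_haplotypes(dh, windows)

    n = dh.n_lines
    E = config.n_environments
    lr_names = config.landrace_names
    lr_idx = np.array([lr_names.index(p) for p in dh.populations])

    genetic = np.zeros((n, E))
    info = matrix.info
    for _, q in truth.qtls.iterrows():
        col = np.flatnonzero(
            (info["window_id"].to_numpy() == q["window_id"])
            & (info["hap_id"].to_numpy() == q["hap_id"])
        )[0]
        x = matrix.scores[:, col].astype(float)
        eff = np.array([q[f"effect_{e}"] for e in config.environment_names])
        genetic += np.outer(x, eff)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11**3]))
    res_sd = np.sqrt(config.residual_variances)
    noise = rng.standard_normal((n, E)) * res_sd[None, :]
    y = (
        config.env_mean_vector[None, :]
        + config.landrace_mean_vector[lr_idx][:, None]
        + genetic
        + truth.polygenic_values.to_numpy()[:, None]
        + noise
    )

    rows = []
    for k, line in enumerate(dh.lines):
        for e, env in enumerate(config.environment_names):
            rows.append((line, env, config.trait, y[k, e]))
        rows.append((line, ACROSS_ENV, config.trait, y[k].mean()))
    return PhenotypeTable(pd.DataFrame(rows, columns=["line", "environment", "trait", "value"]))


# ---------------------------------------------------------------------------
# Convenience


def default_qtl_spec(panel: GenotypePanel, config: SimConfig, n_stable: int = 3,
                     n_interacting: int = 1, n_null: int = 0, effect_size: float = 0.4,
                     min_freq: float = 0.1, max_freq: float = 0.5) -> list[QTLSpec]:
    """Pick well-spread windows whose second-most-common haplotype sits in a
    usable frequency band, and assign alternating stable/interacting patterns."""
    windows = build_windows(panel.marker_map, 10)
    dh = panel.subset_lines(np.array([p != "breeding" for p in panel.populations]))
    catalog, _ = call_haplotypes(dh, windows)
    eligible = []
    for wid, grp in catalog.table.groupby("window_id"):
        grp = grp.sort_values(["count_all", "allele_string"], ascending=[False, True])
        if len(grp) >= 2 and min_freq <= grp.iloc[1]["freq_all"] <= max_freq:
            eligible.append(int(wid))
    total = n_stable + n_interacting + n_null
    if len(eligible) < total:
        raise ValueError(f"only {len(eligible)} eligible windows for {total} QTLs")
    pick = [eligible[i] for i in
            np.linspace(0, len(eligible) - 1, total).round().astype(int)]
    spec = []
    for i, w in enumerate(pick):
        if i < n_stable:
            pattern = "stable+" if i % 2 == 0 else "stable-"
        elif i < n_stable + n_interacting:
            pattern = "interacting"
        else:
            pattern = "null"
        spec.append(QTLSpec(window=w, hap_rank=1,
                            effect_size=0.0 if pattern == "null" else effect_size,
                            pattern=pattern))
    return spec


def simulate_study(config: SimConfig, auto_qtls: bool = True, **qtl_kwargs):
    """Generate a full study: panel, truth, phenotypes."""
    panel = simulate_genotypes(config)
    if auto_qtls and not config.qtl_spec:
        config.qtl_spec = default_qtl_spec(panel, config, **qtl_kwargs)
    truth = plant_qtls(panel, config)
    phenotypes = simulate_phenotypes(panel, truth, config)
    return panel, truth, phenotypes


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["qtl_spec"] = [asdict(q) for q in config.qtl_spec]
    return d
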