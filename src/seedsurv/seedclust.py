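"""Bootstrap seed-clustering: transcripts co-/inversely expressed with a seed gene.

The seed gene is represented by two independent probes. For each seed probe,
samples are bootstrap-resampled B times; per replicate a transcript "hits"
when its Bonferroni-adjusted Spearman correlation with the seed is
significant with the same sign as on the full data. The hit fraction is the
transcript's bootstrap *support*. A transcript's *concordance* is the
smaller of its two supports when the full-data correlation signs agree
across the seed probes, and 0 otherwise. Transcripts are selected when both
supports clear a threshold and the concordance exceeds the empirical
(1−alpha) quantile of a null built by rerunning the whole dual-seed
computation on random pairs of non-seed probes (recording, per pair, the
maximum concordance over transcripts — a familywise-calibrated cut).

Everything is driven by one integer seed through numpy's SeedSequence, so
identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import ExpressionMatrix, RunConfig, logger

CLASS_CO = "co_expressed"
CLASS_INV = "inversely_expressed"
CLASS_NONE = "none"

MIN_SAMPLES = 5


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p from the
    large-sample t approximation, after pairwise removal of missing pairs.

    Raises ``ValueError`` with fewer than 5 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < MIN_SAMPLES:
        raise ValueError(f"only {n} complete pairs; need >= {MIN_SAMPLES}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return rho, float(_t_approx_p(np.array(rho), n))


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via t = rho*sqrt((n-2)/(1-rho^2))."""
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def bonferroni(p_values, m: int) -> np.ndarray:
    """min(1, p*m): familywise Bonferroni adjustment over m transcripts."""
    if m <= 0:
        raise ValueError("number of tests m must be positive")
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * m)


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1, method="average")


def _standardize_rows(r: np.ndarray) -> np.ndarray:
    """Rows centred and scaled to unit variance; constant rows become 0."""
    c = r - r.mean(axis=1, keepdims=True)
    sd = c.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, c / sd, 0.0)
    return z


def _spearman_vs_seeds(x: np.ndarray, seed_rows: np.ndarray) -> np.ndarray:
    """rho of every probe row against every seed row, shape (P, S)."""
    z = _standardize_rows(_rank_rows(x))
    return (z @ z[seed_rows].T) / x.shape[1]


def _bootstrap_support(
    values: np.ndarray,
    seed_rows: np.ndarray,
    B: int,
    alpha: float,
    m_tests: int,
    rng: np.random.Generator,
    resampler=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap support of every probe against every seed row.

    Returns ``(full_rho, support)``, both of shape (n_probes, n_seeds).
    *resampler*, if given, maps (replicate, rng, n) -> sample indices; the
    default draws n samples with replacement. Resamples in which any seed
    row is constant are redrawn.
    """
    if np.isnan(values).any():
        raise ValueError("bootstrap engine requires a complete matrix; impute or drop missing values")
    n_probes, n = values.shape
    if n < MIN_SAMPLES:
        raise ValueError(f"cannot bootstrap with n={n} samples (need >= {MIN_SAMPLES})")
    full_rho = _spearman_vs_seeds(values, seed_rows)
    full_sign = np.sign(full_rho)

    hits = np.zeros((n_probes, len(seed_rows)))
    for b in range(B):
        for _ in range(100):
            idx = resampler(b, rng, n) if resampler is not None else rng.integers(0, n, n)
            xb = values[:, idx]
            if (np.ptp(xb[seed_rows], axis=1) > 0).all():
                break
        else:  # pragma: no cover - requires pathological input
            raise RuntimeError("could not draw a resample with non-constant seeds")
        nb = xb.shape[1]
        rho_b = _spearman_vs_seeds(xb, seed_rows)
        p_adj = bonferroni(_t_approx_p(rho_b, nb), m_tests)
        hits += (p_adj < alpha) & (np.sign(rho_b) == full_sign) & (full_sign != 0)
    return full_rho, hits / B


def bootstrap_association(
    m: ExpressionMatrix,
    seed_probe: str,
    B: int,
    alpha: float,
    rng_seed: int,
    resampler=None,
) -> pd.DataFrame:
    """Per-probe full-data rho, Bonferroni-adjusted p and bootstrap support
    against one seed probe. The seed itself is excluded from the candidates.
    """
    seed_row = m.probe_index(seed_probe)
    m_tests = m.n_probes - 1
    rng = np.random.default_rng(rng_seed)
    full_rho, support = _bootstrap_support(
        m.values, np.array([seed_row]), B, alpha, m_tests, rng, resampler=resampler
    )
    out = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "rho": full_rho[:, 0],
            "p_adj": bonferroni(_t_approx_p(full_rho[:, 0], m.n_samples), m_tests),
            "support": support[:, 0],
        }
    )
    return out[out["probe_id"] != seed_probe].reset_index(drop=True)


@dataclass
class NullDistribution:
    """Max-concordance statistics from random seed pairs, and the
    empirical (1−alpha) quantile used as the selection cut."""

    concordance_values: np.ndarray
    quantile_cut: float


def _concordance(full_rho: np.ndarray, support: np.ndarray, cols: tuple[int, int]) -> np.ndarray:
    """min(support) over the two seed columns where full-data signs agree
    (and are non-zero), else 0."""
    s1, s2 = cols
    agree = (np.sign(full_rho[:, s1]) == np.sign(full_rho[:, s2])) & (np.sign(full_rho[:, s1]) != 0)
    return np.where(agree, np.minimum(support[:, s1], support[:, s2]), 0.0)


def random_seed_null(
    m: ExpressionMatrix,
    R: int,
    B: int,
    alpha: float,
    rng_seed: int,
    exclude: tuple[str, str] | None = None,
) -> NullDistribution:
    """Null distribution of the max-over-transcripts concordance from R
    random pairs of distinct non-seed probes treated as seeds.

    All pairs share one pass of bootstrap-ranked matrices, so the cost is a
    single dual-seed run regardless of R.
    """
    if R < 20:
        warnings.warn(f"null_sims R={R} < 20: the null quantile will be unstable", stacklevel=2)
    rng = np.random.default_rng(rng_seed)
    excl_rows = {m.probe_index(p) for p in exclude} if exclude else set()
    candidates = np.array([i for i in range(m.n_probes) if i not in excl_rows])
    if len(candidates) < 2 * R:
        raise ValueError(f"need at least {2 * R} non-seed probes for R={R} null pairs")
    pair_rows = np.stack([rng.choice(candidates, size=2, replace=False) for _ in range(R)])
    seed_rows = pair_rows.reshape(-1)
    m_tests = m.n_probes - 2
    full_rho, support = _bootstrap_support(m.values, seed_rows, B, alpha, m_tests, rng)

    maxima = np.empty(R)
    for r in range(R):
        conc = _concordance(full_rho, support, (2 * r, 2 * r + 1))
        mask = np.ones(m.n_probes, dtype=bool)
        mask[pair_rows[r]] = False
        mask[list(excl_rows)] = False
        maxima[r] = conc[mask].max()
    cut = float(np.quantile(maxima, 1.0 - alpha))
    logger.info("random_seed_null: R=%d, quantile_cut=%.4f", R, cut)
    return NullDistribution(concordance_values=maxima, quantile_cut=cut)


@dataclass
class SeedClusterResult:
    """Per-transcript associations with both seed probes plus the selected
    co-/inversely expressed gene lists (collapsed to unique symbols)."""

    records: pd.DataFrame
    null: NullDistribution
    co_expressed_genes: list[str]
    inversely_expressed_genes: list[str]
    seed_probes: tuple[str, str]
    params: dict


def seed_cluster(
    m: ExpressionMatrix,
    seed_probe_1: str,
    seed_probe_2: str,
    config: RunConfig,
) -> SeedClusterResult:
    """Dual-seed bootstrap clustering with random-pair null calibration.

    A transcript is ``co_expressed`` when both full-data correlations are
    positive, both supports reach ``config.support_threshold`` and the
    concordance exceeds the null cut; ``inversely_expressed`` analogously
    with both correlations negative.
    """
    if seed_probe_1 == seed_probe_2:
        raise ValueError("the two seed probes must be distinct")
    r1 = m.probe_index(seed_probe_1)
    r2 = m.probe_index(seed_probe_2)
    seed_rho, _ = spearman(m.values[r1], m.values[r2])
    if seed_rho < 0.2:
        warnings.warn(
            f"seed probes correlate at rho={seed_rho:.2f} (<0.2); "
            "they may not target the same transcript", stacklevel=2,
        )
    B, alpha = config.bootstrap_reps, config.alpha
    m_tests = m.n_probes - 2
    ss_assoc, ss_null = np.random.SeedSequence(config.rng_seed).spawn(2)
    rng = np.random.default_rng(ss_assoc)
    full_rho, support = _bootstrap_support(m.values, np.array([r1, r2]), B, alpha, m_tests, rng)
    null = random_seed_null(
        m, R=config.null_sims, B=B, alpha=alpha,
        rng_seed=ss_null, exclude=(seed_probe_1, seed_probe_2),
    )

    conc = _concordance(full_rho, support, (0, 1))
    n = m.n_samples
    p1 = bonferroni(_t_approx_p(full_rho[:, 0], n), m_tests)
    p2 = bonferroni(_t_approx_p(full_rho[:, 1], n), m_tests)
    both_support = (support[:, 0] >= config.support_threshold) & (support[:, 1] >= config.support_threshold)
    selected = both_support & (conc > null.quantile_cut)
    cls = np.full(m.n_probes, CLASS_NONE, dtype=object)
    cls[selected & (full_rho[:, 0] > 0) & (full_rho[:, 1] > 0)] = CLASS_CO
    cls[selected & (full_rho[:, 0] < 0) & (full_rho[:, 1] < 0)] = CLASS_INV

    records = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "gene_symbol": m.gene_symbols if m.gene_symbols is not None else m.probe_ids,
            "rho_seed1": full_rho[:, 0],
            "rho_seed2": full_rho[:, 1],
            "p_seed1": p1,
            "p_seed2": p2,
            "support_seed1": support[:, 0],
            "support_seed2": support[:, 1],
            "concordance": conc,
            "class": cls,
        }
    )
    is_seed = records["probe_id"].isin([seed_probe_1, seed_probe_2])
    records = records[~is_seed].reset_index(drop=True)

    # a gene is selected if ANY of its probes is selected
    co = records.loc[records["class"] == CLASS_CO, "gene_symbol"]
    inv = records.loc[records["class"] == CLASS_INV, "gene_symbol"]
    co_genes = sorted(set(co))
    inv_genes = sorted(set(inv))
    logger.info(
        "seed_cluster: B=%d R=%d alpha=%g support>=%g -> %d co-expressed, %d inversely expressed probes "
        "(%d / %d genes)",
        B, config.null_sims, alpha, config.support_threshold,
        int((records["class"] == CLASS_CO).sum()), int((records["class"] == CLASS_INV).sum()),
        len(co_genes), len(inv_genes),
    )
    return SeedClusterResult(
        records=records,
        null=null,
        co_expressed_genes=co_genes,
        inversely_expressed_genes=inv_genes,
        seed_probes=(seed_probe_1, seed_probe_2),
        params={
            "bootstrap_reps": B, "alpha": alpha,
            "support_threshold": config.support_threshold,
            "null_sims": config.null_sims, "rng_seed": config.rng_seed,
        },
    )
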