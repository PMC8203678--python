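"""Fitness-defect scoring: gene counts -> per-screen FD scores and calls.

The model follows the standard pooled-screen count workflow: uptag and
downtag counts are summed per gene; samples are normalized by
median-of-ratios size factors; per-gene negative-binomial dispersions are
estimated by method-of-moments and shrunk toward a mean-dispersion trend;
each screen (treatment replicates vs diluent/date-matched control replicates)
is fit by NB maximum likelihood to give a log2 fold change with a Wald
standard error; the LFC is shrunk toward zero with an empirical-Bayes prior;
and the fitness-defect score is FD = -(shrunken LFC), so depleted (sensitive)
strains score positive.  FD >= 1 (at least two-fold depletion) calls a strain
sensitive, FD <= -1 resistant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counting import TagCountMatrix
from .synthetic import ScreenDesign, StrainCatalog

__all__ = [
    "GeneCountMatrix",
    "FitnessTable",
    "collapse_tags",
    "size_factors",
    "estimate_dispersions",
    "fit_screen",
    "shrink_lfc",
    "estimate_prior_scale",
    "fd_table",
    "fd_matrix",
    "flag_screens",
]

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
PRIOR_VAR_FLOOR = 0.25  # tau^2 floor, log2^2 units


@dataclass
class GeneCountMatrix:
    """Gene x sample counts (uptag + downtag summed), tied to a design."""

    counts: pd.DataFrame
    design: ScreenDesign

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.design.samples) - set(self.counts.columns)
        if missing:
            raise ValueError(f"design samples missing from counts: {sorted(missing)[:5]}")


@dataclass
class FitnessTable:
    """Tidy per-(gene, screen) fitness results.

    Columns: gene, screen_id, fd, raw_lfc, se, p, fdr, call.  FD is in -log2
    units; call is sensitive (fd >= threshold, inclusive), resistant
    (fd <= -threshold) or neutral.
    """

    frame: pd.DataFrame
    fd_threshold: float = 1.0

    def screen(self, screen_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["screen_id"] == screen_id]
        if sub.empty:
            raise KeyError(f"unknown screen_id {screen_id!r}")
        return sub

    def sensitive_genes(self, screen_id: str) -> list[str]:
        sub = self.screen(screen_id)
        return list(sub.loc[sub["call"] == "sensitive", "gene"])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, fd_threshold: float = 1.0) -> "FitnessTable":
        return cls(pd.read_csv(path, sep="\t"), fd_threshold=fd_threshold)


def fd_matrix(table: FitnessTable) -> pd.DataFrame:
    """Pivot a FitnessTable to genes x screens of FD scores."""
    return table.frame.pivot(index="gene", columns="screen_id", values="fd")


# ---------------------------------------------------------------------------
# Collapse tags to genes
# ---------------------------------------------------------------------------

def collapse_tags(tag_counts: TagCountMatrix, catalog: StrainCatalog, design: ScreenDesign) -> GeneCountMatrix:
    """Sum each strain's uptag and downtag rows into one gene row.

    A tag absent from the matrix counts as zero; a matrix tag absent from the
    catalog is an error.
    """
    counts = tag_counts.counts
    known = set(catalog.tags)
    stray = [t for t in counts.index if t not in known]
    if stray:
        raise ValueError(f"tags not in catalog: {stray[:5]}")
    up = counts.reindex(catalog.frame["uptag"]).fillna(0).to_numpy()
    down = counts.reindex(catalog.frame["downtag"]).fillna(0).to_numpy()
    frame = pd.DataFrame(
        (up + down).astype(np.int64),
        index=pd.Index(catalog.genes, name="gene"),
        columns=counts.columns,
    )
    return GeneCountMatrix(counts=frame, design=design)


# ---------------------------------------------------------------------------
# Size factors (median-of-ratios)
# ---------------------------------------------------------------------------

def size_factors(gene_counts: GeneCountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    factor_j = median over genes positive in every sample of
    count_gj / geometric_mean_g(count_g.).  Reported unnormalized.
    """
    counts = gene_counts.counts if isinstance(gene_counts, GeneCountMatrix) else gene_counts
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; consider a pseudocount"
        )
    logs = np.log(arr[positive])
    geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def _fit_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mu on informative genes."""
    ok = (alpha > DISPERSION_FLOOR * 10) & (mu > 0)
    if ok.sum() < 2:
        return max(float(np.median(alpha)), DISPERSION_FLOOR), 0.0
    x = 1.0 / mu[ok]
    y = alpha[ok]
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0 = max(float(coef[0]), DISPERSION_FLOOR)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def estimate_dispersions(
    gene_counts: GeneCountMatrix,
    sf: pd.Series,
    design: ScreenDesign | None = None,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion: method-of-moments, trend-shrunk in log space.

    Residual variance is computed on normalized counts after subtracting the
    mean of each replicate group (a screen's treatments, or a diluent+date
    control batch).  The raw estimate (s^2 - xi*mu)/mu^2 is floored at 1e-8
    and averaged in log space with the fitted trend a0 + a1/mu.  Genes with
    zero residual variance return the floor; all-zero genes get the trend.
    """
    design = design or gene_counts.design
    counts = gene_counts.counts
    q = counts.to_numpy(dtype=float) / sf.reindex(counts.columns).to_numpy()
    groups = design.replicate_groups()
    col_pos = {s: i for i, s in enumerate(counts.columns)}
    resid = np.zeros_like(q)
    dof = -0.0
    n_groups = 0
    for members in groups.values():
        idx = [col_pos[s] for s in members if s in col_pos]
        if not idx:
            continue
        block = q[:, idx]
        resid[:, idx] = block - block.mean(axis=1, keepdims=True)
        n_groups += 1
    n_samples = q.shape[1]
    dof = max(n_samples - n_groups, 1)
    if n_samples - n_groups < 1:
        raise ValueError("need >= 2 samples in at least one replicate group")
    s2 = (resid**2).sum(axis=1) / dof
    mu = q.mean(axis=1)
    xi = float(np.mean(1.0 / sf.to_numpy()))  # Poisson part of var(count/sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - xi * mu) / mu**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.maximum(raw, DISPERSION_FLOOR)
    a0, a1 = _fit_trend(mu, raw)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-12), a0)
    trend = np.maximum(trend, DISPERSION_FLOOR)
    w = float(shrink_weight)
    final = np.exp((1 - w) * np.log(raw) + w * np.log(trend))
    final = np.where(s2 == 0, DISPERSION_FLOOR, final)  # constant counts
    final = np.where(mu == 0, trend, final)  # all-zero genes
    return pd.Series(np.maximum(final, DISPERSION_FLOOR), index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# Per-screen NB fit
# ---------------------------------------------------------------------------

def _nb_group_fit(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 30):
    """Vectorized NB MLE of the normalized group mean q per gene.

    Newton iterations on u = ln q: score = sum_j (y - mu)/(1 + alpha*mu),
    info = sum_j mu/(1 + alpha*mu) with mu = sf_j * q.  Genes with all-zero
    counts get q floored at half a count (for finite LFCs) and info 0.
    Returns (q, info).
    """
    totals = y.sum(axis=1)
    sf_sum = sf.sum()
    q = np.maximum(totals / sf_sum, 0.5 / sf_sum)
    u = np.log(q)
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = sf[None, :] * np.exp(u)[:, None]
        denom = 1.0 + a * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        u = u + np.clip(step, -4.0, 4.0)
    q = np.exp(u)
    q = np.maximum(q, 0.5 / sf_sum)
    mu = sf[None, :] * q[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return q, info


def fit_screen(
    gene_counts: GeneCountMatrix,
    sf: pd.Series,
    dispersions: pd.Series,
    design: ScreenDesign | None = None,
    screen_id: str = "",
) -> pd.DataFrame:
    """NB fit of one screen: per-gene raw log2 fold change, Wald se, p.

    Treatment replicates are fit jointly against the screen's diluent/date
    matched controls.  Genes with zero counts in both conditions get
    raw_lfc = 0, p = 1.
    """
    design = design or gene_counts.design
    if screen_id not in design.screen_ids:
        raise KeyError(f"unknown screen_id {screen_id!r}")
    t_samples = design.treatment_samples(screen_id)
    c_samples = design.control_samples(screen_id)
    counts = gene_counts.counts
    alpha = dispersions.reindex(counts.index).to_numpy(dtype=float)
    y_t = counts[t_samples].to_numpy(dtype=float)
    y_c = counts[c_samples].to_numpy(dtype=float)
    sf_t = sf.reindex(t_samples).to_numpy(dtype=float)
    sf_c = sf.reindex(c_samples).to_numpy(dtype=float)
    q_t, info_t = _nb_group_fit(y_t, sf_t, alpha)
    q_c, info_c = _nb_group_fit(y_c, sf_c, alpha)
    raw_lfc = (np.log(q_t) - np.log(q_c)) / LOG2
    with np.errstate(divide="ignore"):
        var_ln = 1.0 / np.maximum(info_t, 1e-300) + 1.0 / np.maximum(info_c, 1e-300)
    se = np.sqrt(var_ln) / LOG2
    both_zero = (y_t.sum(axis=1) == 0) & (y_c.sum(axis=1) == 0)
    raw_lfc = np.where(both_zero, 0.0, raw_lfc)
    se = np.where(both_zero, np.inf, se)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(raw_lfc) / se, np.inf)
    p = np.where(both_zero, 1.0, 2.0 * stats.norm.sf(np.where(np.isfinite(z), z, np.inf)))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {"raw_lfc": raw_lfc, "se": se, "p": p}, index=counts.index
    )


# ---------------------------------------------------------------------------
# LFC shrinkage
# ---------------------------------------------------------------------------

def estimate_prior_scale(raw_lfc: np.ndarray, se: np.ndarray, trim: float = 0.05) -> float:
    """Prior variance tau^2 for LFC shrinkage.

    Trimmed second moment of the raw LFC population minus the mean squared
    standard error, floored at PRIOR_VAR_FLOOR.
    """
    raw_lfc = np.asarray(raw_lfc, dtype=float)
    se = np.asarray(se, dtype=float)
    finite = np.isfinite(raw_lfc) & np.isfinite(se)
    if not finite.any():
        return PRIOR_VAR_FLOOR
    vals = np.sort(raw_lfc[finite])
    k = int(len(vals) * trim)
    trimmed = vals[k : len(vals) - k] if len(vals) > 2 * k else vals
    m2 = float(np.mean(trimmed**2)) if len(trimmed) else 0.0
    mean_se2 = float(np.mean(se[finite] ** 2))
    return max(m2 - mean_se2, PRIOR_VAR_FLOOR)


_GH_NODES, _GH_WEIGHTS = hermegauss(64)  # probabilists' Hermite


def shrink_lfc(
    raw_lfc: np.ndarray,
    se: np.ndarray,
    tau2: float | None = None,
    prior: str = "cauchy",
) -> np.ndarray:
    """Empirical-Bayes shrinkage of raw LFCs toward zero.

    prior="cauchy" (default): posterior mean under a zero-centered Cauchy
    prior with scale tau, computed by Gauss-Hermite quadrature.  The heavy
    tail leaves decisively non-null effects nearly unshrunk while pulling
    noise-level estimates toward zero.

    prior="normal": closed form raw * tau^2 / (tau^2 + se^2).

    Both contract (|shrunk| <= |raw|), preserve sign, and reduce to the raw
    estimate as se -> 0.  tau^2 defaults to ``estimate_prior_scale``.
    """
    raw_lfc = np.atleast_1d(np.asarray(raw_lfc, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    if (se < 0).any():
        raise ValueError("se must be >= 0")
    if tau2 is None:
        tau2 = estimate_prior_scale(raw_lfc, se)
    if prior == "normal":
        with np.errstate(invalid="ignore"):
            out = raw_lfc * tau2 / (tau2 + se**2)
        return np.where(np.isfinite(se), out, 0.0)
    if prior != "cauchy":
        raise ValueError(f"unknown prior {prior!r}")
    out = np.array(raw_lfc, dtype=float)
    active = np.isfinite(se) & (se > 0) & np.isfinite(raw_lfc)
    out[~np.isfinite(se)] = 0.0
    if active.any():
        r = raw_lfc[active][:, None]
        s = se[active][:, None]
        beta = r + s * _GH_NODES[None, :]
        prior_w = 1.0 / (1.0 + beta**2 / tau2)
        num = (_GH_WEIGHTS[None, :] * prior_w * beta).sum(axis=1)
        den = (_GH_WEIGHTS[None, :] * prior_w).sum(axis=1)
        post = num / den
        # quadrature safety: contraction and sign preservation are exact for
        # the true posterior; enforce them against numerical error
        lo = np.minimum(0.0, raw_lfc[active])
        hi = np.maximum(0.0, raw_lfc[active])
        out[active] = np.clip(post, lo, hi)
    return out


# ---------------------------------------------------------------------------
# FD table
# ---------------------------------------------------------------------------

def flag_screens(
    gene_counts: GeneCountMatrix,
    sf: pd.Series,
    design: ScreenDesign | None = None,
    min_replicate_r: float = 0.7,
) -> dict[str, float]:
    """QC: minimum pairwise Pearson r of log normalized counts among each
    screen's treatment replicates.  Screens below ``min_replicate_r`` are
    flagged (returned with their r) but never dropped."""
    design = design or gene_counts.design
    flagged: dict[str, float] = {}
    counts = gene_counts.counts
    for screen_id in design.screen_ids:
        samples = design.treatment_samples(screen_id)
        if len(samples) < 2:
            continue
        q = counts[samples].to_numpy(dtype=float) / sf.reindex(samples).to_numpy()
        logs = np.log1p(q)
        r = np.corrcoef(logs.T)
        min_r = float(r[np.triu_indices_from(r, k=1)].min())
        if min_r < min_replicate_r:
            flagged[screen_id] = min_r
            logger.warning("screen %s flagged: replicate r=%.3f", screen_id, min_r)
    return flagged


def fd_table(
    gene_counts: GeneCountMatrix,
    design: ScreenDesign | None = None,
    fd_threshold: float = 1.0,
    prior: str = "cauchy",
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> FitnessTable:
    """Full fitness pipeline: size factors, dispersions, per-screen NB fits,
    LFC shrinkage, FD scores, BH FDR within each screen, and calls.

    FD = -(shrunken LFC); call is sensitive iff FD >= fd_threshold
    (inclusive: 'at least two-fold'), resistant iff FD <= -fd_threshold.
    """
    if fd_threshold < 0:
        raise ValueError("fd_threshold must be >= 0")
    design = design or gene_counts.design
    if sf is None:
        sf = size_factors(gene_counts)
    if dispersions is None:
        dispersions = estimate_dispersions(gene_counts, sf, design)
    frames = []
    for screen_id in design.screen_ids:
        fit = fit_screen(gene_counts, sf, dispersions, design, screen_id)
        raw = fit["raw_lfc"].to_numpy()
        se = fit["se"].to_numpy()
        shrunk = shrink_lfc(raw, se, prior=prior)
        fd = -shrunk
        fdr = multipletests(fit["p"].to_numpy(), method="fdr_bh")[1]
        call = np.where(
            fd >= fd_threshold, "sensitive", np.where(fd <= -fd_threshold, "resistant", "neutral")
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene": fit.index,
                    "screen_id": screen_id,
                    "fd": fd,
                    "raw_lfc": raw,
                    "se": se,
                    "p": fit["p"].to_numpy(),
                    "fdr": fdr,
                    "call": call,
                }
            )
        )
        logger.info(
            "screen %s: %d sensitive / %d genes",
            screen_id,
            int((call == "sensitive").sum()),
            len(call),
        )
    frame = pd.concat(frames, ignore_index=True)
    return FitnessTable(frame=frame, fd_threshold=fd_threshold)
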