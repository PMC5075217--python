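"""Unsupervised per-amplicon zygosity calling.

For each amplicon a_j the caller picks the L amplicons from *other* genes
whose log-coverage vectors across samples are most Sn-correlated with
cov(a_j) (partners must clear a correlation threshold T, chosen so that
every analysable site keeps at least one callable amplicon).  Each partner
yields a Theil-Sen regression of log cov(a_j) on log cov(partner); a sample
is an outlier for that model when its Sn-studentized residual exceeds a
Student-t quantile (alpha 0.02 low side / 0.05 high side, df = n - 2).  An
outlier supports a heterozygous deletion (duplication) only if the simple
Bayes factor against the wild-type line — normal likelihoods around the
fitted line and around the line shifted by log 0.5 (log 1.5) — exceeds 1.
A state is called when at least N of the L models agree (N = 4, L = 5 by
default).  Homozygous deletions are pre-empted by the QC mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .coverage import CoverageMatrix
from .robust import (DegenerateInputError, sn_correlation_matrix,
                     studentized_residuals, theil_sen)

__all__ = ["UnsupervisedConfig", "InsufficientSamplesError", "log_coverage",
           "candidate_correlations", "choose_corr_threshold", "partner_counts",
           "select_partners", "call_amplicons", "merge_calls"]

LOG_HALF = float(np.log(0.5))
LOG_1P5 = float(np.log(1.5))

_MIN_MODEL_SAMPLES = 8  # per-model pairwise subsets smaller than this are skipped


class InsufficientSamplesError(RuntimeError):
    """Fewer QC-passed samples than the caller's minimum cohort size."""


@dataclass
class UnsupervisedConfig:
    n_partners: int = 5          # L
    votes_required: int = 4      # N
    corr_threshold: float | None = None  # None -> choose on the data
    alpha_del: float = 0.02
    alpha_dup: float = 0.05
    max_cnv_frequency: float = 0.20
    min_samples: int = 25
    allow_small_cohort: bool = False
    pseudocount: float = 0.5
    # At most this many partners may come from any single gene, so that a
    # CNV spanning one partner gene can never supply the votes_required
    # votes on its own.  None -> votes_required - 1.
    max_partners_per_gene: int | None = None

    def __post_init__(self):
        if not 1 <= self.votes_required <= self.n_partners:
            raise ValueError("need 1 <= votes_required <= n_partners")
        for a in (self.alpha_del, self.alpha_dup):
            if not 0.0 < a < 0.5:
                raise ValueError("alphas must lie in (0, 0.5)")
        if self.corr_threshold is not None and not 0.0 <= self.corr_threshold < 1.0:
            raise ValueError("corr_threshold must lie in [0, 1)")

    @property
    def gene_cap(self) -> int:
        if self.max_partners_per_gene is not None:
            return self.max_partners_per_gene
        return max(1, self.votes_required - 1)


def log_coverage(matrix: CoverageMatrix, pseudocount: float = 0.5,
                 impute_masked: bool = False) -> np.ndarray:
    """Natural-log counts (zeros replaced by the pseudocount); (m, n) array.

    With ``impute_masked`` the value of every masked cell is replaced by the
    amplicon's median log coverage over its usable cells, so masked values
    never reach an estimator that needs rectangular input (correlations).
    """
    counts = matrix.counts.to_numpy(dtype=float)
    logc = np.log(np.where(counts > 0, counts, pseudocount))
    if impute_masked:
        mask = matrix.mask.to_numpy()
        for i in np.flatnonzero(~mask.all(axis=1)):
            ok = mask[i]
            if ok.any():
                logc[i, ~ok] = np.median(logc[i, ok])
    return logc


def candidate_correlations(matrix: CoverageMatrix, usable: np.ndarray,
                           pseudocount: float = 0.5) -> np.ndarray:
    """Sn-correlation matrix of log coverages; pairs within the same gene and
    rows not in ``usable`` are NaN (never candidates)."""
    panel = matrix.panel
    logc = log_coverage(matrix, pseudocount, impute_masked=True)
    corr = np.full((len(panel), len(panel)), np.nan)
    idx = np.flatnonzero(usable)
    if idx.size >= 2:
        sub = sn_correlation_matrix(logc[idx])
        corr[np.ix_(idx, idx)] = sub
    gene = np.array([a.gene for a in panel.amplicons])
    same_gene = gene[:, None] == gene[None, :]
    corr[same_gene] = np.nan
    return corr


def _kth_best(corr: np.ndarray, panel, k: int, gene_cap: int) -> np.ndarray:
    """Per row, the k-th largest candidate correlation after keeping at most
    ``gene_cap`` candidates per gene (-inf if fewer than k remain)."""
    genes = np.array([a.gene for a in panel.amplicons])
    out = np.full(corr.shape[0], -np.inf)
    for i, row in enumerate(corr):
        pooled = []
        for gene in np.unique(genes):
            vals = row[(genes == gene) & np.isfinite(row)]
            if vals.size:
                pooled.extend(np.sort(vals)[-gene_cap:])
        if len(pooled) >= k:
            out[i] = np.sort(pooled)[-k]
    return out


def choose_corr_threshold(corr: np.ndarray, matrix: CoverageMatrix,
                          usable: np.ndarray, n_partners: int,
                          gene_cap: int | None = None) -> float:
    """Largest T on a 0.01 grid such that every analysable site keeps at
    least one amplicon with n_partners candidates above T (respecting the
    per-gene partner cap).  Falls back to 0 (with a warning) when no
    positive T works."""
    panel = matrix.panel
    if gene_cap is None:
        gene_cap = n_partners
    kth = _kth_best(corr, panel, n_partners, gene_cap)
    site_best = []
    for site, amps in panel.sites.items():
        rows = [panel.index_of(a) for a in amps if usable[panel.index_of(a)]]
        if rows:
            site_best.append(max(kth[r] for r in rows))
    limit = min(site_best) if site_best else -np.inf
    grid = np.round(np.arange(0.99, -0.001, -0.01), 2)
    for t in grid:
        if limit > t:
            return float(t)
    warnings.warn("no positive correlation threshold keeps every site "
                  "analysable; falling back to T = 0")
    return 0.0


def partner_counts(corr: np.ndarray, panel, threshold: float,
                   gene_cap: int) -> np.ndarray:
    """Number of candidate partners above the threshold, per amplicon,
    counting at most ``gene_cap`` per candidate gene."""
    genes = np.array([a.gene for a in panel.amplicons])
    with np.errstate(invalid="ignore"):
        above = np.isfinite(corr) & (corr > threshold)
    counts = np.zeros(corr.shape[0], dtype=int)
    for gene in np.unique(genes):
        counts += np.minimum(above[:, genes == gene].sum(axis=1), gene_cap)
    return counts


def select_partners(amp_index: int, corr: np.ndarray, matrix: CoverageMatrix,
                    config: UnsupervisedConfig, threshold: float) -> list[int]:
    """Top-L candidate partner indices for one amplicon, ranked by
    correlation (desc), then genomic distance (desc), then id — deterministic
    ties — taking at most ``gene_cap`` partners from any single gene.
    Returns fewer than L if not enough clear the threshold."""
    panel = matrix.panel
    row = corr[amp_index]
    cand = np.flatnonzero(np.isfinite(row) & (row > threshold))
    amp_id = panel.ids[amp_index]

    def key(j: int):
        return (-row[j], -panel.distance(amp_id, panel.ids[j]), panel.ids[j])

    chosen: list[int] = []
    per_gene: dict[str, int] = {}
    for j in sorted(cand.tolist(), key=key):
        gene = panel.amplicons[j].gene
        if per_gene.get(gene, 0) >= config.gene_cap:
            continue
        chosen.append(j)
        per_gene[gene] = per_gene.get(gene, 0) + 1
        if len(chosen) == config.n_partners:
            break
    return chosen


def call_amplicons(matrix: CoverageMatrix, config: UnsupervisedConfig,
                   corr: np.ndarray | None = None,
                   threshold: float | None = None) -> tuple[pd.DataFrame, float]:
    """Run the caller over every usable amplicon.

    Returns (calls, T): one row per (amplicon, sample) with the state,
    supporting vote count and the median Bayes factor K of the supporting
    models; T is the correlation threshold used.
    """
    panel = matrix.panel
    samples = matrix.samples
    n = len(samples)
    if n < config.min_samples and not config.allow_small_cohort:
        raise InsufficientSamplesError(
            f"{n} QC-passed samples < minimum cohort of {config.min_samples}")

    mask = matrix.mask.to_numpy()
    usable = mask.any(axis=1)
    if corr is None:
        corr = candidate_correlations(matrix, usable, config.pseudocount)
    if threshold is None:
        threshold = (config.corr_threshold if config.corr_threshold is not None
                     else choose_corr_threshold(corr, matrix, usable,
                                                config.n_partners,
                                                config.gene_cap))
    logc = log_coverage(matrix, config.pseudocount)

    rows = []
    for j in np.flatnonzero(usable):
        partners = select_partners(j, corr, matrix, config, threshold)
        if len(partners) < config.n_partners:
            continue  # partnerless amplicons are QC business, not calls
        votes_del = np.zeros(n, dtype=int)
        votes_dup = np.zeros(n, dtype=int)
        k_del = [[] for _ in range(n)]
        k_dup = [[] for _ in range(n)]
        for p in partners:
            both = mask[j] & mask[p]
            if both.sum() < _MIN_MODEL_SAMPLES:
                continue
            x = logc[p, both]
            y = logc[j, both]
            try:
                model = theil_sen(x, y)
                r = studentized_residuals(model, x, y)
            except DegenerateInputError:
                continue
            df = both.sum() - 2
            t_low = _stats.t.ppf(1.0 - config.alpha_del, df)
            t_high = _stats.t.ppf(1.0 - config.alpha_dup, df)
            resid = model.residuals(x, y)
            s = model.residual_scale
            # Bayes factor of the shifted line vs the fitted line, normal
            # likelihoods with the common residual scale.
            bf_del = np.exp(_stats.norm.logpdf(resid, LOG_HALF, s)
                            - _stats.norm.logpdf(resid, 0.0, s))
            bf_dup = np.exp(_stats.norm.logpdf(resid, LOG_1P5, s)
                            - _stats.norm.logpdf(resid, 0.0, s))
            sample_idx = np.flatnonzero(both)
            low = (r < -t_low) & (bf_del > 1.0)
            high = (r > t_high) & (bf_dup > 1.0)
            votes_del[sample_idx] += low
            votes_dup[sample_idx] += high
            for si, lo_i, hi_i, bd, bu in zip(sample_idx, low, high, bf_del, bf_dup):
                if lo_i:
                    k_del[si].append(bd)
                if hi_i:
                    k_dup[si].append(bu)
        amp_id = panel.ids[j]
        for i, sample in enumerate(samples):
            if not mask[j, i]:
                state, votes, k = "HOM_DEL", config.n_partners, float("inf")
            elif votes_del[i] >= config.votes_required:
                state, votes, k = "HET_DEL", int(votes_del[i]), float(np.median(k_del[i]))
            elif votes_dup[i] >= config.votes_required:
                state, votes, k = "DUP", int(votes_dup[i]), float(np.median(k_dup[i]))
            else:
                state, votes, k = "NORMAL", int(max(votes_del[i], votes_dup[i])), 0.0
            rows.append((amp_id, sample, state, votes, k))
    calls = pd.DataFrame(rows, columns=["amplicon", "sample", "state",
                                        "votes", "bayes_factor_K"])
    return calls, float(threshold)


def merge_calls(calls: pd.DataFrame, panel) -> pd.DataFrame:
    """Collapse consecutive same-state non-NORMAL amplicon calls (panel
    order, within one gene) into site-run rows.  Duplication runs confined
    to a single site are flagged ``single_site_dup``."""
    cols = ["sample", "gene", "state", "first_site", "last_site", "n_amplicons",
            "first_index", "last_index", "min_votes", "bayes_factor",
            "single_site_dup", "stage"]
    if calls.empty:
        return pd.DataFrame(columns=cols)
    order = {a: i for i, a in enumerate(panel.ids)}
    runs = []
    for sample, grp in calls.groupby("sample", sort=True):
        grp = grp[grp["state"] != "NORMAL"]
        if grp.empty:
            continue
        grp = grp.assign(_idx=[order[a] for a in grp["amplicon"]]).sort_values("_idx")
        current = None
        for _, row in grp.iterrows():
            idx = row["_idx"]
            gene = panel.gene_of(row["amplicon"])
            if (current is not None and row["state"] == current["state"]
                    and gene == current["gene"] and idx == current["last_index"] + 1):
                current["last_index"] = idx
                current["n_amplicons"] += 1
                current["min_votes"] = min(current["min_votes"], row["votes"])
                current["ks"].append(row["bayes_factor_K"])
            else:
                if current is not None:
                    runs.append(current)
                current = {"sample": sample, "gene": gene, "state": row["state"],
                           "first_index": idx, "last_index": idx, "n_amplicons": 1,
                           "min_votes": row["votes"], "ks": [row["bayes_factor_K"]]}
        if current is not None:
            runs.append(current)
    out = []
    for r in runs:
        sites = {panel.site_of(panel.ids[i])
                 for i in range(r["first_index"], r["last_index"] + 1)}
        single_dup = r["state"] == "DUP" and len(sites) == 1
        out.append((r["sample"], r["gene"], r["state"],
                    panel.site_of(panel.ids[r["first_index"]]),
                    panel.site_of(panel.ids[r["last_index"]]),
                    r["n_amplicons"], r["first_index"], r["last_index"],
                    r["min_votes"], float(np.median(r["ks"])), single_dup,
                    "unsupervised"))
    return pd.DataFrame(out, columns=cols)
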