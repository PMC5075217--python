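"""Supervised site-level CNV classification against a control set.

Per amplicon, the log coverage is normalised by the mean log coverage of a
cluster of k highly correlated amplicons from other genes (Pearson
correlation when the control set exceeds 20 samples, the robust
Sn-correlation otherwise).  Three models describe the normalised statistic
x_j: the wild-type model (Hodges–Lehmann location, Sn scale over controls)
and deletion/duplication models shifted by log 0.5 / log 1.5 with variances
corrected by 2 and 2/3 (log-Poisson delta method).  A test sample's site is

1. *suspicious* for a state when every amplicon of the site is admissible
   under that state's model (per-amplicon chi-square(1) test at
   0.05 / expected number of altered amplicons);
2. confirmed against the wild type when the squared normalised Euclidean
   distance to the wild-type profile rejects it (chi-square with one degree
   of freedom per amplicon, Benjamini–Hochberg across all suspicious
   site-sample pairs);
3. called when the Bayes factor of the state's model over the wild-type
   model (independent normal densities per amplicon, equal priors) reaches
   the threshold (100 by default).

Test samples left without calls join the control set and the procedure
repeats until it converges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .coverage import CoverageMatrix
from .robust import (benjamini_hochberg, hodges_lehmann, sn_correlation_matrix,
                     sn_scale)
from .unsupervised import LOG_1P5, LOG_HALF, log_coverage

__all__ = ["SupervisedConfig", "InsufficientControlsError", "CopyNumberModel",
           "AmpliconModels", "split_control_test", "cluster_amplicons",
           "normalize_amplicon", "fit_models", "run_supervised", "merge_site_calls"]


class InsufficientControlsError(RuntimeError):
    """Fewer CNV-free control samples than the model requires."""


@dataclass
class SupervisedConfig:
    cluster_size: int = 5            # k
    max_cluster_per_gene: int = 3    # spread the cluster over genes
    pearson_min_control: int = 20    # Pearson when |Control| > this
    min_control: int = 20
    admissibility_alpha: float = 0.05
    fdr_level: float = 0.05
    bayes_factor_threshold: float = 100.0
    max_iterations: int = 5

    def __post_init__(self):
        if min(self.cluster_size, self.min_control, self.max_iterations) < 1:
            raise ValueError("sizes must be positive")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")


@dataclass(frozen=True)
class CopyNumberModel:
    label: str
    location: float
    scale: float

    def __post_init__(self):
        if self.scale <= 0.0:
            raise ValueError("model scale must be strictly positive")


@dataclass(frozen=True)
class AmpliconModels:
    amplicon: str
    normal: CopyNumberModel
    het_del: CopyNumberModel
    dup: CopyNumberModel


def split_control_test(samples, amplicon_calls: pd.DataFrame | None = None,
                       control_samples=None,
                       config: SupervisedConfig | None = None):
    """Partition samples into (control, test).

    An explicit control list wins; otherwise a sample is suspected of
    carrying a CNV (test set) when the unsupervised stage flagged any of its
    amplicons, and is a control otherwise.
    """
    config = config or SupervisedConfig()
    samples = list(samples)
    if control_samples is not None:
        control = [s for s in samples if s in set(control_samples)]
        test = [s for s in samples if s not in set(control_samples)]
    else:
        if amplicon_calls is None:
            raise ValueError("need unsupervised calls or an explicit control list")
        flagged = set(amplicon_calls.loc[amplicon_calls["state"] != "NORMAL",
                                         "sample"])
        control = [s for s in samples if s not in flagged]
        test = [s for s in samples if s in flagged]
    if len(control) < config.min_control:
        raise InsufficientControlsError(
            f"{len(control)} control samples < required {config.min_control}; "
            "supply an a-priori CNV-free control list")
    return control, test


def _control_correlations(logc_controls: np.ndarray, use_pearson: bool) -> np.ndarray:
    if use_pearson:
        with np.errstate(invalid="ignore"):
            return np.corrcoef(logc_controls)
    return sn_correlation_matrix(logc_controls)


def cluster_amplicons(amp_index: int, corr: np.ndarray, panel,
                      usable: np.ndarray, config: SupervisedConfig) -> list[int]:
    """Top-k positively correlated candidate amplicons from other genes."""
    gene = panel.amplicons[amp_index].gene
    row = corr[amp_index]
    cand = [j for j in np.flatnonzero(usable)
            if j != amp_index and panel.amplicons[j].gene != gene
            and np.isfinite(row[j]) and row[j] > 0.0]
    cand.sort(key=lambda j: (-row[j], panel.ids[j]))
    chosen: list[int] = []
    per_gene: dict[str, int] = {}
    for j in cand:
        g = panel.amplicons[j].gene
        if per_gene.get(g, 0) >= config.max_cluster_per_gene:
            continue
        chosen.append(j)
        per_gene[g] = per_gene.get(g, 0) + 1
        if len(chosen) == config.cluster_size:
            break
    return chosen


def normalize_amplicon(logc: np.ndarray, amp_index: int, cluster: list[int],
                       mask: np.ndarray) -> np.ndarray:
    """x_j per sample: log cov(a_j) minus the mean log coverage of the
    cluster (usable cluster cells only); NaN where nothing is usable."""
    n = logc.shape[1]
    x = np.full(n, np.nan)
    for i in range(n):
        if not mask[amp_index, i]:
            continue
        cl = [j for j in cluster if mask[j, i]]
        if not cl:
            continue
        x[i] = logc[amp_index, i] - np.mean(logc[cl, i])
    return x


def fit_models(amplicon: str, control_x: np.ndarray) -> AmpliconModels | None:
    """Three copy-number models from control values of x_j; None when the
    controls are degenerate (zero Sn scale)."""
    vals = control_x[np.isfinite(control_x)]
    if vals.size < 3:
        return None
    loc = hodges_lehmann(vals)
    scale = sn_scale(vals)
    if scale <= 0.0:
        return None
    return AmpliconModels(
        amplicon=amplicon,
        normal=CopyNumberModel("NORMAL", loc, scale),
        het_del=CopyNumberModel("HET_DEL", loc + LOG_HALF, scale * math.sqrt(2.0)),
        dup=CopyNumberModel("DUP", loc + LOG_1P5, scale * math.sqrt(2.0 / 3.0)),
    )


def _classify_pass(matrix, config, control, test, pseudocount,
                   exclude_sites=()):
    """One full supervised pass; returns (site_calls df, models kept)."""
    panel = matrix.panel
    samples = matrix.samples
    col = {s: i for i, s in enumerate(samples)}
    mask = matrix.mask.to_numpy()
    usable = mask.any(axis=1)
    logc = log_coverage(matrix, pseudocount, impute_masked=True)
    ctrl_cols = [col[s] for s in control]
    test_cols = [col[s] for s in test]

    use_pearson = len(control) > config.pearson_min_control
    corr = np.full((len(panel), len(panel)), np.nan)
    idx = np.flatnonzero(usable)
    if idx.size >= 2:
        corr[np.ix_(idx, idx)] = _control_correlations(
            logc[np.ix_(idx, ctrl_cols)], use_pearson)

    models: dict[int, AmpliconModels] = {}
    x_all = np.full((len(panel), len(samples)), np.nan)
    for j in idx:
        cluster = cluster_amplicons(j, corr, panel, usable, config)
        if not cluster:
            continue
        x = normalize_amplicon(logc, j, cluster, mask)
        fitted = fit_models(panel.ids[j], x[ctrl_cols])
        if fitted is None:
            continue
        models[j] = fitted
        x_all[j] = x

    n_modelled = len(models)
    expected_altered = max(1.0, len(test) * n_modelled / 2.0)
    alpha_adm = config.admissibility_alpha / expected_altered
    chi1 = _stats.chi2.ppf(1.0 - alpha_adm, df=1)

    candidates = []  # (sample, site, gene, m, p, susp_del, susp_dup, z-data)
    excluded = set(exclude_sites)
    for site, amps in panel.sites.items():
        if site in excluded:
            continue
        site_rows = [panel.index_of(a) for a in amps if panel.index_of(a) in models]
        if not site_rows:
            continue
        gene = panel.site_gene[site]
        for s in test:
            i = col[s]
            rows = [j for j in site_rows if mask[j, i] and np.isfinite(x_all[j, i])]
            if not rows:
                continue
            x = x_all[rows, i]
            mods = [models[j] for j in rows]
            z2 = {}
            for label in ("normal", "het_del", "dup"):
                locs = np.array([getattr(m, label).location for m in mods])
                scales = np.array([getattr(m, label).scale for m in mods])
                z2[label] = (x - locs) ** 2 / scales ** 2
            susp_del = bool(np.all(z2["het_del"] <= chi1))
            susp_dup = bool(np.all(z2["dup"] <= chi1))
            if not (susp_del or susp_dup):
                continue
            ned2 = float(np.sum(z2["normal"]))
            p = float(_stats.chi2.sf(ned2, df=len(rows)))
            log_bf = {}
            for label in ("het_del", "dup"):
                m_loc = np.array([getattr(m, label).location for m in mods])
                m_sc = np.array([getattr(m, label).scale for m in mods])
                n_loc = np.array([m.normal.location for m in mods])
                n_sc = np.array([m.normal.scale for m in mods])
                log_bf[label] = float(
                    np.sum(_stats.norm.logpdf(x, m_loc, m_sc))
                    - np.sum(_stats.norm.logpdf(x, n_loc, n_sc)))
            candidates.append({"sample": s, "site": site, "gene": gene,
                               "n_amplicons": len(rows), "p": p,
                               "susp_del": susp_del, "susp_dup": susp_dup,
                               "log_bf_del": log_bf["het_del"],
                               "log_bf_dup": log_bf["dup"]})

    rows = []
    if candidates:
        adj = benjamini_hochberg([c["p"] for c in candidates])
        log_thresh = math.log(config.bayes_factor_threshold)
        for c, adj_p in zip(candidates, adj):
            state = "NORMAL"
            log_bf = -math.inf
            if c["susp_del"]:
                log_bf = c["log_bf_del"]
                state_candidate = "HET_DEL"
            if c["susp_dup"] and c["log_bf_dup"] > log_bf:
                log_bf = c["log_bf_dup"]
                state_candidate = "DUP"
            if adj_p <= config.fdr_level and log_bf >= log_thresh:
                state = state_candidate
            rows.append((c["sample"], c["site"], c["gene"], state, True,
                         c["p"], float(adj_p),
                         float(np.exp(min(log_bf, 700.0))), c["n_amplicons"]))
    site_calls = pd.DataFrame(rows, columns=[
        "sample", "site", "gene", "state", "suspicious", "p", "adj_p",
        "bayes_factor", "n_amplicons"])
    return site_calls, models


def run_supervised(matrix: CoverageMatrix, config: SupervisedConfig,
                   control, test, pseudocount: float = 0.5,
                   exclude_sites=()):
    """Iterate the supervised pass, growing the control set with test
    samples found CNV-free, until convergence or ``max_iterations``.

    Returns (site_calls, final_control, n_iterations).
    """
    control = list(control)
    test = list(test)
    site_calls = pd.DataFrame(columns=["sample", "site", "gene", "state",
                                       "suspicious", "p", "adj_p",
                                       "bayes_factor", "n_amplicons"])
    iterations = 0
    while iterations < config.max_iterations:
        iterations += 1
        site_calls, _ = _classify_pass(matrix, config, control, test,
                                       pseudocount, exclude_sites)
        if not test:
            break
        called = set(site_calls.loc[site_calls["state"] != "NORMAL", "sample"])
        clean = [s for s in test if s not in called]
        if not clean:
            break
        control = control + clean
        test = [s for s in test if s in called]
        if not test:
            break
    return site_calls, control, iterations


def merge_site_calls(site_calls: pd.DataFrame, panel) -> pd.DataFrame:
    """Collapse adjacent called sites (same sample/gene/state) into runs in
    the same shape as the unsupervised merged report."""
    cols = ["sample", "gene", "state", "first_site", "last_site", "n_amplicons",
            "first_index", "last_index", "adj_p", "bayes_factor",
            "single_site_dup", "stage"]
    called = site_calls[site_calls["state"] != "NORMAL"]
    if called.empty:
        return pd.DataFrame(columns=cols)
    site_order = {s: i for i, s in enumerate(panel.sites)}
    spans = {s: (min(panel.index_of(a) for a in amps),
                 max(panel.index_of(a) for a in amps))
             for s, amps in panel.sites.items()}
    out = []
    for (sample, gene, state), grp in called.groupby(["sample", "gene", "state"],
                                                     sort=True):
        grp = grp.assign(_ord=[site_order[s] for s in grp["site"]]).sort_values("_ord")
        current = None
        finished = []
        for _, row in grp.iterrows():
            if current is not None and row["_ord"] == current["last_ord"] + 1:
                current["last_ord"] = row["_ord"]
                current["sites"].append(row["site"])
                current["n_amplicons"] += int(row["n_amplicons"])
                current["adj_p"] = max(current["adj_p"], float(row["adj_p"]))
                current["bf"] = min(current["bf"], float(row["bayes_factor"]))
            else:
                if current is not None:
                    finished.append(current)
                current = {"last_ord": row["_ord"], "sites": [row["site"]],
                           "n_amplicons": int(row["n_amplicons"]),
                           "adj_p": float(row["adj_p"]),
                           "bf": float(row["bayes_factor"])}
        finished.append(current)
        for run in finished:
            first_site, last_site = run["sites"][0], run["sites"][-1]
            out.append((sample, gene, state, first_site, last_site,
                        run["n_amplicons"], spans[first_site][0],
                        spans[last_site][1], run["adj_p"], run["bf"],
                        state == "DUP" and len(run["sites"]) == 1, "supervised"))
    return pd.DataFrame(out, columns=cols)
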