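"""Input-data quality control.

Order of the full pass (as orchestrated by the pipeline):

1. drop samples with fewer than ``min_sample_reads`` total reads;
2. flag homozygous-deletion cells (count below ``homdel_max_cov`` on an
   otherwise well-covered amplicon) and mask them out of all statistics;
3. fail amplicons with low mean coverage or without enough correlating
   partner amplicons (partner availability is supplied by the unsupervised
   stage); sites whose amplicons all fail are excluded everywhere;
4. drop "irregular" samples whose within-gene normalised coverage profile
   deviates from the cohort in more than half of the genes.

The irregular-sample test per gene: within-gene normalised log coverages are
compared to a per-amplicon Hodges–Lehmann reference with Sn scales; the sum
of the ceil(0.8 m) smallest squared standardised coordinates is referred to
a chi-square with that many degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .coverage import CoverageMatrix
from .robust import _sn_batch, hodges_lehmann

__all__ = ["QcThresholds", "QcReport", "QcError",
           "filter_samples_by_reads", "call_homozygous_deletions",
           "amplicon_mean_coverage", "filter_amplicons",
           "detect_irregular_samples"]


class QcError(RuntimeError):
    """Fatal quality-control failure (e.g. no sample survives filtering)."""


@dataclass
class QcThresholds:
    min_sample_reads: int = 15000
    min_amplicon_mean_cov: float = 50.0
    homdel_max_cov: int = 10
    trimmed_fraction: float = 0.8
    # The chi-square reference for the per-gene statistic assumes independent
    # coordinates, but amplicons within a gene share efficiency-group factors,
    # so the statistic's tail is heavier than chi-square.  The default level
    # is therefore set far below a textbook 0.01: genuine profile distortions
    # sit orders of magnitude beyond any threshold, while typical cohorts
    # should lose essentially no samples to this filter.
    gene_alpha: float = 1e-6

    def __post_init__(self):
        if min(self.min_sample_reads, self.min_amplicon_mean_cov,
               self.homdel_max_cov, self.gene_alpha) <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0.0 < self.trimmed_fraction <= 1.0:
            raise ValueError("trimmed_fraction must lie in (0, 1]")


@dataclass
class QcReport:
    failed_samples: list = field(default_factory=list)     # (sample, reason)
    failed_amplicons: list = field(default_factory=list)   # (amplicon, reason)
    excluded_sites: list = field(default_factory=list)
    homdel_cells: list = field(default_factory=list)       # (amplicon, sample)
    irregular_samples: list = field(default_factory=list)  # (sample, n_failed_genes)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sample, reason in self.failed_samples:
                fh.write(f"failed_sample\t{sample}\t{reason}\n")
            for sample, n in self.irregular_samples:
                fh.write(f"irregular_sample\t{sample}\tfailed_genes={n}\n")
            for amp, reason in self.failed_amplicons:
                fh.write(f"failed_amplicon\t{amp}\t{reason}\n")
            for site in self.excluded_sites:
                fh.write(f"excluded_site\t{site}\t.\n")
            for amp, sample in self.homdel_cells:
                fh.write(f"homdel_cell\t{amp}\t{sample}\n")


def filter_samples_by_reads(matrix: CoverageMatrix, thresholds: QcThresholds,
                            report: QcReport) -> CoverageMatrix:
    """Remove samples whose total read count is below ``min_sample_reads``."""
    totals = matrix.counts.sum(axis=0)
    bad = [s for s in matrix.samples if totals[s] < thresholds.min_sample_reads]
    for s in bad:
        report.failed_samples.append((s, f"total_reads={int(totals[s])}"))
    if len(bad) == len(matrix.samples):
        raise QcError(
            "all samples fall below the minimum read count "
            f"({thresholds.min_sample_reads}); inspect the dataset")
    return matrix.drop_samples(bad) if bad else matrix


def call_homozygous_deletions(matrix: CoverageMatrix, thresholds: QcThresholds,
                              report: QcReport) -> list[tuple[str, str]]:
    """Flag and mask cells with count < homdel_max_cov on amplicons whose
    across-sample mean coverage is high enough to trust the absence."""
    counts = matrix.counts.to_numpy()
    eligible = counts.mean(axis=1) >= thresholds.min_amplicon_mean_cov
    low = counts < thresholds.homdel_max_cov
    cells = []
    rows, cols = np.nonzero(low & eligible[:, None])
    amp_ids, samples = matrix.amplicon_ids, matrix.samples
    for r, c in zip(rows, cols):
        cells.append((amp_ids[r], samples[c]))
        matrix.mask.iat[r, c] = False
    report.homdel_cells.extend(cells)
    return cells


def amplicon_mean_coverage(matrix: CoverageMatrix) -> np.ndarray:
    """Per-amplicon mean count over cells not masked as homozygous deletions."""
    counts = matrix.counts.to_numpy(dtype=float)
    mask = matrix.mask.to_numpy()
    n_ok = mask.sum(axis=1)
    sums = np.where(mask, counts, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(n_ok > 0, sums / np.maximum(n_ok, 1), 0.0)
    return means


def filter_amplicons(matrix: CoverageMatrix, thresholds: QcThresholds,
                     partner_ok: np.ndarray, report: QcReport) -> list[str]:
    """Fail amplicons with low mean coverage or too few correlating
    partners; record sites left without any callable amplicon.

    Low-coverage amplicons are masked outright (their counts are too noisy
    to serve any purpose).  Partner-poor amplicons are only excluded from
    *calling*: their coverage is sound and they stay in the candidate pool
    as predictors for others — masking them would cascade, stripping
    partners from their whole correlation group.  Returns the ids of all
    failed (uncallable) amplicons.
    """
    means = amplicon_mean_coverage(matrix)
    already_dead = ~matrix.mask.to_numpy().any(axis=1)
    failed = []
    for i, amp in enumerate(matrix.amplicon_ids):
        if already_dead[i]:
            failed.append(amp)
            continue
        if means[i] < thresholds.min_amplicon_mean_cov:
            report.failed_amplicons.append((amp, f"low_coverage={means[i]:.1f}"))
            failed.append(amp)
            matrix.mask.loc[amp] = False
        elif not partner_ok[i]:
            report.failed_amplicons.append((amp, "no_partners"))
            failed.append(amp)
    failed_set = set(failed)
    for site, amps in matrix.panel.sites.items():
        if site not in report.excluded_sites and \
                all(a in failed_set for a in amps):
            report.excluded_sites.append(site)
    return failed


def passing_amplicons(matrix: CoverageMatrix) -> list[str]:
    """Amplicons with at least one usable cell."""
    ok = matrix.mask.to_numpy().any(axis=1)
    return [a for a, keep in zip(matrix.amplicon_ids, ok) if keep]


def detect_irregular_samples(matrix: CoverageMatrix, thresholds: QcThresholds,
                             report: QcReport) -> list[str]:
    """Find samples whose per-gene normalised profile deviates in more than
    n/2 of the n genes (only applied when n > 2 genes are testable)."""
    panel = matrix.panel
    passing = set(passing_amplicons(matrix))
    genes = {}
    for amp in passing:
        genes.setdefault(panel.gene_of(amp), []).append(amp)
    genes = {g: amps for g, amps in genes.items() if len(amps) >= 2}
    n_genes = len(genes)
    if n_genes <= 2:
        return []

    samples = matrix.samples
    fail_counts = dict.fromkeys(samples, 0)
    for gene, amps in genes.items():
        counts = matrix.counts.loc[amps].to_numpy(dtype=float)
        mask = matrix.mask.loc[amps].to_numpy()
        # masked cells contribute nothing to the gene totals, so their stored
        # values never reach the statistic
        totals = np.where(mask, counts, 0.0).sum(axis=0)
        if np.any(totals <= 0):
            continue
        v = np.log(np.maximum(counts, 0.5) / totals)
        m_amp, n_smp = v.shape
        # Per-amplicon reference location and scale across samples,
        # restricted to usable cells.
        y = np.full(m_amp, np.nan)
        s = np.full(m_amp, np.nan)
        for k in range(m_amp):
            vals = v[k, mask[k]]
            if vals.size >= 3:
                y[k] = hodges_lehmann(vals)
                s[k] = _sn_batch(vals[None, :])[0]
        usable_amp = np.isfinite(y) & np.isfinite(s) & (s > 0)
        if usable_amp.sum() < 2:
            continue
        for j, sample in enumerate(samples):
            rows = usable_amp & mask[:, j]
            m_j = int(rows.sum())
            if m_j < 2:
                continue
            z = (v[rows, j] - y[rows]) ** 2 / s[rows] ** 2
            k_keep = math.ceil(thresholds.trimmed_fraction * m_j)
            stat = np.sort(z)[:k_keep].sum()
            if stat > _stats.chi2.ppf(1.0 - thresholds.gene_alpha, df=k_keep):
                fail_counts[sample] += 1

    irregular = [s for s in samples if fail_counts[s] > n_genes / 2.0]
    report.irregular_samples.extend((s, fail_counts[s]) for s in irregular)
    return irregular
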