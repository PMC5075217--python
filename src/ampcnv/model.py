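"""Model/Results interface over the two-stage pipeline.

``AmpliconCnvModel`` holds a coverage matrix plus configuration;
``fit()`` runs QC, the unsupervised per-amplicon caller, the control/test
split and the supervised site classifier, and returns a ``CnvResults``
object carrying the per-amplicon calls, the per-site calls, the merged
report and the QC report, with ``summary()`` and ``save()``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import qc as _qc
from . import supervised as _sup
from . import unsupervised as _unsup
from .coverage import CoverageMatrix, load_coverage_tsv
from .panel import load_panel
from .qc import QcReport, QcThresholds
from .supervised import SupervisedConfig
from .unsupervised import UnsupervisedConfig

__all__ = ["AmpliconCnvModel", "CnvResults"]

MODES = ("unsupervised_only", "supervised_only", "both")

REPORT_COLUMNS = ["sample", "gene", "state", "first_site", "last_site",
                  "n_amplicons", "first_index", "last_index", "adj_p",
                  "bayes_factor", "votes", "stage"]


@dataclass
class CnvResults:
    """Outcome of one fitted run."""

    report: pd.DataFrame                 # default report (suppressions applied)
    full_report: pd.DataFrame            # including flagged single-site dups
    amplicon_calls: pd.DataFrame
    site_calls: pd.DataFrame
    qc_report: QcReport
    corr_threshold: float | None
    control_samples: list = field(default_factory=list)
    test_samples: list = field(default_factory=list)
    iterations: int = 0
    n_samples_analysed: int = 0
    params: dict = field(default_factory=dict)

    def summary(self) -> str:
        qc = self.qc_report
        lines = [
            "Amplicon CNV calling summary",
            "============================",
            f"samples analysed:        {self.n_samples_analysed}",
            f"samples failed QC:       {len(qc.failed_samples)}",
            f"irregular samples:       {len(qc.irregular_samples)}",
            f"amplicons failed QC:     {len(qc.failed_amplicons)}",
            f"sites excluded:          {len(qc.excluded_sites)}",
            f"homozygous-deletion cells: {len(qc.homdel_cells)}",
        ]
        if self.corr_threshold is not None:
            lines.append(f"correlation threshold T: {self.corr_threshold:.2f}")
        if self.control_samples or self.test_samples:
            lines.append(f"control/test split:      "
                         f"{len(self.control_samples)}/{len(self.test_samples)} "
                         f"({self.iterations} iteration(s))")
        n_unsup = int((self.amplicon_calls["state"] != "NORMAL").sum()) \
            if len(self.amplicon_calls) else 0
        lines.append(f"non-normal amplicon calls (unsupervised): {n_unsup}")
        lines.append(f"reported CNV calls:      {len(self.report)}")
        if len(self.report):
            lines.append("")
            lines.append(self.report[REPORT_COLUMNS].to_string(index=False))
        return "\n".join(lines)

    def save(self, outdir) -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        self.report[REPORT_COLUMNS].to_csv(
            os.path.join(outdir, "calls.tsv"), sep="\t", index=False)
        self.full_report.to_csv(
            os.path.join(outdir, "calls_full.tsv"), sep="\t", index=False)
        self.amplicon_calls.to_csv(
            os.path.join(outdir, "amplicon_calls.tsv"), sep="\t", index=False)
        self.site_calls.to_csv(
            os.path.join(outdir, "site_calls.tsv"), sep="\t", index=False)
        self.qc_report.to_tsv(os.path.join(outdir, "qc_report.tsv"))
        with open(os.path.join(outdir, "params.json"), "w") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True)
            fh.write("\n")


class AmpliconCnvModel:
    """Two-stage CNV caller over one coverage matrix (one sequencing run).

    Parameters
    ----------
    coverage : CoverageMatrix
        Amplicon x sample read counts for one run.
    qc_thresholds, unsupervised_config, supervised_config : optional
        Stage configurations; defaults follow the published thresholds.
    mode : {"both", "unsupervised_only", "supervised_only"}
    control_samples : list of str, optional
        A-priori CNV-free samples.  Required for ``supervised_only``;
        otherwise overrides the unsupervised control/test split.
    """

    def __init__(self, coverage: CoverageMatrix, *,
                 qc_thresholds: QcThresholds | None = None,
                 unsupervised_config: UnsupervisedConfig | None = None,
                 supervised_config: SupervisedConfig | None = None,
                 mode: str = "both",
                 control_samples=None):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if mode == "supervised_only" and not control_samples:
            raise ValueError("supervised_only mode requires an explicit control list")
        self.coverage = coverage
        self.qc_thresholds = qc_thresholds or QcThresholds()
        self.unsupervised_config = unsupervised_config or UnsupervisedConfig()
        self.supervised_config = supervised_config or SupervisedConfig()
        self.mode = mode
        self.control_samples = list(control_samples) if control_samples else None

    @classmethod
    def from_files(cls, panel_path, coverage_path, **kwargs) -> "AmpliconCnvModel":
        panel = load_panel(panel_path)
        return cls(load_coverage_tsv(coverage_path, panel), **kwargs)

    # -- QC ---------------------------------------------------------------

    def _amplicon_filter_pass(self, matrix, report):
        """Correlation / threshold / partner-availability pass.  Only
        low-coverage amplicons leave the candidate pool; partner-poor ones
        stay as predictors (see qc.filter_amplicons), so one pass suffices
        and the whole QC is idempotent."""
        cfg = self.unsupervised_config
        means = _qc.amplicon_mean_coverage(matrix)
        usable = (matrix.mask.to_numpy().any(axis=1)
                  & (means >= self.qc_thresholds.min_amplicon_mean_cov))
        corr = _unsup.candidate_correlations(matrix, usable, cfg.pseudocount)
        threshold = (cfg.corr_threshold if cfg.corr_threshold is not None
                     else _unsup.choose_corr_threshold(
                         corr, matrix, usable, cfg.n_partners, cfg.gene_cap))
        partner_ok = _unsup.partner_counts(corr, matrix.panel, threshold,
                                           cfg.gene_cap) >= cfg.n_partners
        _qc.filter_amplicons(matrix, self.qc_thresholds, partner_ok, report)
        return corr, float(threshold)

    def _run_qc(self, report: QcReport):
        matrix = self.coverage.copy()
        matrix = _qc.filter_samples_by_reads(matrix, self.qc_thresholds, report)
        _qc.call_homozygous_deletions(matrix, self.qc_thresholds, report)
        corr, threshold = self._amplicon_filter_pass(matrix, report)

        irregular = _qc.detect_irregular_samples(matrix, self.qc_thresholds, report)
        if irregular:
            matrix = matrix.drop_samples(irregular)
            if len(matrix.samples) == 0:
                raise _qc.QcError("all samples are irregular; inspect the dataset")
            corr, threshold = self._amplicon_filter_pass(matrix, report)
        return matrix, corr, threshold

    # -- fit --------------------------------------------------------------

    def fit(self) -> CnvResults:
        report = QcReport()
        matrix, corr, threshold = self._run_qc(report)

        amplicon_calls = pd.DataFrame(
            columns=["amplicon", "sample", "state", "votes", "bayes_factor_K"])
        unsup_runs = pd.DataFrame()
        if self.mode != "supervised_only":
            amplicon_calls, threshold = _unsup.call_amplicons(
                matrix, self.unsupervised_config, corr=corr, threshold=threshold)
            unsup_runs = _unsup.merge_calls(amplicon_calls, matrix.panel)

        site_calls = pd.DataFrame(
            columns=["sample", "site", "gene", "state", "suspicious", "p",
                     "adj_p", "bayes_factor", "n_amplicons"])
        sup_runs = pd.DataFrame()
        control: list = []
        test: list = []
        iterations = 0
        if self.mode != "unsupervised_only":
            control, test = _sup.split_control_test(
                matrix.samples,
                amplicon_calls=None if self.control_samples else amplicon_calls,
                control_samples=self.control_samples,
                config=self.supervised_config)
            site_calls, control, iterations = _sup.run_supervised(
                matrix, self.supervised_config, control, test,
                pseudocount=self.unsupervised_config.pseudocount,
                exclude_sites=report.excluded_sites)
            sup_runs = _sup.merge_site_calls(site_calls, matrix.panel)

        full_report = _combine_reports(unsup_runs, sup_runs, matrix.panel)
        keep = ~full_report["single_site_dup"].astype(bool) \
            if len(full_report) else pd.Series(dtype=bool)
        default_report = full_report[keep] if len(full_report) else full_report

        params = {
            "mode": self.mode,
            "qc": asdict(self.qc_thresholds),
            "unsupervised": asdict(self.unsupervised_config),
            "supervised": asdict(self.supervised_config),
            "corr_threshold": threshold,
            "control_samples": sorted(control),
        }
        return CnvResults(
            report=default_report.reset_index(drop=True),
            full_report=full_report.reset_index(drop=True),
            amplicon_calls=amplicon_calls,
            site_calls=site_calls,
            qc_report=report,
            corr_threshold=threshold,
            control_samples=list(control),
            test_samples=[s for s in matrix.samples if s not in set(control)],
            iterations=iterations,
            n_samples_analysed=len(matrix.samples),
            params=params,
        )


_MERGE_GAP = 1  # uncalled amplicons bridged inside one reported event


def _combine_reports(unsup_runs: pd.DataFrame, sup_runs: pd.DataFrame,
                     panel=None) -> pd.DataFrame:
    """Union of the two stages' merged runs.

    Same-sample, same-gene, same-state runs whose amplicon spans overlap (or
    are separated by at most one uncalled amplicon — a single dropout should
    not split a reported event) collapse into one row; a row supported by
    both stages gets stage='both' and carries the supervised evidence.
    """
    cols = REPORT_COLUMNS + ["single_site_dup"]
    runs = []
    for df in (unsup_runs, sup_runs):
        if len(df):
            runs.extend(df.to_dict("records"))
    if not runs:
        return pd.DataFrame(columns=cols)

    groups: dict = {}
    for r in runs:
        groups.setdefault((r["sample"], r["gene"], r["state"]), []).append(r)

    rows = []
    for (sample, gene, state), grp in sorted(groups.items()):
        grp.sort(key=lambda r: (r["first_index"], r["last_index"]))
        cluster = []
        for r in grp + [None]:
            if cluster and (r is None
                            or r["first_index"] > cluster[-1]["hi"] + _MERGE_GAP + 1):
                merged = _merge_cluster(sample, gene, state, cluster, panel)
                rows.append(merged)
                cluster = []
            if r is not None:
                cluster.append({"hi": max(r["last_index"],
                                          cluster[-1]["hi"] if cluster else -1),
                                "run": r})
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols].sort_values(["sample", "first_index"]).reset_index(drop=True)


def _merge_cluster(sample, gene, state, cluster, panel) -> dict:
    members = [c["run"] for c in cluster]
    first = min(r["first_index"] for r in members)
    last = max(r["last_index"] for r in members)
    stages = {r["stage"] for r in members}
    stage = "both" if len(stages) > 1 else next(iter(stages))
    votes = [r["min_votes"] for r in members if "min_votes" in r]
    adj_ps = [r["adj_p"] for r in members
              if "adj_p" in r and np.isfinite(r.get("adj_p", np.nan))]
    bfs = [r["bayes_factor"] for r in members if "bayes_factor" in r]
    if panel is not None:
        first_site = panel.site_of(panel.ids[first])
        last_site = panel.site_of(panel.ids[last])
        sites = {panel.site_of(panel.ids[i]) for i in range(first, last + 1)}
        single_dup = state == "DUP" and len(sites) == 1
    else:
        first_site = min((r["first_site"] for r in members), default="")
        last_site = max((r["last_site"] for r in members), default="")
        single_dup = all(bool(r.get("single_site_dup")) for r in members)
    return {"sample": sample, "gene": gene, "state": state,
            "first_site": first_site, "last_site": last_site,
            "n_amplicons": last - first + 1,
            "first_index": first, "last_index": last,
            "adj_p": min(adj_ps) if adj_ps else np.nan,
            "bayes_factor": max(bfs) if bfs else np.nan,
            "votes": max(votes) if votes else np.nan,
            "single_site_dup": single_dup, "stage": stage}
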