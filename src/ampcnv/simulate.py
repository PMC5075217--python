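"""Coverage simulator with the statistical structure the caller assumes.

The amplification model: the yield of amplicon j in sample i is

    mu_ij = m_ij * d_j * ((1 + e_j * f_gi) / (1 + e_j)) ** c

where m_ij is the copy-number multiplier (1 for wild type, 0.5 het deletion,
1.5 het duplication, 2.0 hom duplication, 0 hom deletion), d_j the amplicon's
target depth, e_j its amplification efficiency, c the number of PCR cycles
and f_gi a per-sample condition factor shared by all amplicons of efficiency
group g.  Exponential amplification makes log coverage highly sensitive to
the condition factor, so amplicons sharing a group are strongly correlated
across samples while groups are nearly independent — exactly the premise the
caller exploits.  Counts are Poisson around mu (an optional lognormal
over-dispersion knob exists but defaults off).

The absolute magnitude of the exponential amplification is folded into the
per-amplicon depth d_j (lognormal around the configured per-run mean
coverage), since only relative yields matter after sequencing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix
from .panel import Amplicon, AmpliconPanel

__all__ = ["SimulationParams", "CnvEvent", "TruthSet", "default_panel",
           "simulate", "random_events", "score_calls",
           "variance_correction_ratio"]

ALLOWED_MULTIPLIERS = (0.0, 0.5, 1.5, 2.0)


@dataclass(frozen=True)
class CnvEvent:
    """A CNV spanning a contiguous run of sites within one gene."""

    sample: str
    gene: str
    sites: tuple  # consecutive site_ids
    multiplier: float

    def __post_init__(self):
        if self.multiplier not in ALLOWED_MULTIPLIERS:
            raise ValueError(f"multiplier must be one of {ALLOWED_MULTIPLIERS}")


@dataclass
class TruthSet:
    """Expansion of the injected events to per-cell multipliers, plus the
    generator's efficiency-group assignment (simulation metadata)."""

    events: list
    multipliers: pd.DataFrame  # amplicon x sample, default 1.0
    amplicon_groups: np.ndarray | None = None


@dataclass
class SimulationParams:
    """Defaults model one sequencing run of a disease-gene assay: 48 samples,
    a ~130-amplicon 3-gene panel, a per-run mean depth of 500 reads per
    amplicon (per-sample averages land inside the typical 120-1200 window),
    lognormal amplicon-to-amplicon depth spread, and a small within-run
    condition jitter (run-to-run condition shifts are far larger, which is
    why each run is analysed separately)."""

    n_samples: int = 48
    panel: AmpliconPanel | None = None  # None -> default_panel()
    n_cycles: int = 25
    mean_coverage: float = 500.0
    amplicon_depth_sd: float = 0.25     # lognormal sd of per-amplicon depth
    efficiency_groups: int = 6
    efficiency_range: tuple = (0.5, 1.0)
    efficiency_spread: float = 0.01
    sample_condition_sd: float = 0.02
    overdispersion_sd: float = 0.0
    cnv_events: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2 or self.n_cycles < 1 or self.efficiency_groups < 1:
            raise ValueError("invalid simulation sizes")
        if self.mean_coverage <= 0 or self.amplicon_depth_sd < 0:
            raise ValueError("invalid coverage parameters")


def default_panel(n_genes: int = 3, n_amplicons: int = 130,
                  amplicon_length: int = 275, seed: int = 7) -> AmpliconPanel:
    """Synthetic multi-gene panel with exon-level sites of 1-5 amplicons,
    mirroring a typical disease-gene assay (~130 amplicons over 3 genes)."""
    rng = np.random.default_rng(seed)
    per_gene = [n_amplicons // n_genes] * n_genes
    per_gene[0] += n_amplicons - sum(per_gene)
    amplicons = []
    for g in range(n_genes):
        gene = f"GENE{g + 1}"
        chrom = f"chr{g + 1}"
        pos = 10_000
        left, exon = per_gene[g], 1
        while left > 0:
            size = min(int(rng.integers(1, 6)), left)
            site = f"{gene}_ex{exon}"
            for _ in range(size):
                start = pos
                end = start + amplicon_length
                amplicons.append(Amplicon(
                    f"{gene}_amp{len([a for a in amplicons if a.gene == gene]) + 1:03d}",
                    chrom, start, end, gene, site))
                pos = end + int(rng.integers(20, 120))
            pos += int(rng.integers(500, 3000))  # intron gap
            left -= size
            exon += 1
    return AmpliconPanel(amplicons)


def _expand_truth(panel: AmpliconPanel, samples, events) -> TruthSet:
    mult = pd.DataFrame(1.0, index=panel.ids, columns=list(samples))
    for ev in events:
        if ev.sample not in mult.columns:
            raise ValueError(f"event sample {ev.sample!r} not in sample list")
        for site in ev.sites:
            if panel.site_gene.get(site) != ev.gene:
                raise ValueError(f"site {site!r} is not in gene {ev.gene!r}")
            for amp in panel.sites[site]:
                mult.at[amp, ev.sample] = ev.multiplier
    # the caller assumes each site is altered in at most ~20 % of samples
    for site, amps in panel.sites.items():
        frac = (mult.loc[amps] != 1.0).any(axis=0).mean()
        if frac > 0.2 + 1e-9:
            raise ValueError(
                f"site {site}: CNV carrier fraction {frac:.2f} exceeds the "
                "20 % model assumption")
    return TruthSet(list(events), mult)


def simulate(params: SimulationParams) -> tuple[CoverageMatrix, TruthSet]:
    """Draw a coverage matrix and its truth set.  Deterministic in
    (params, params.seed)."""
    panel = params.panel if params.panel is not None else default_panel()
    rng = np.random.default_rng(params.seed)
    m = len(panel)
    samples = [f"S{i + 1:02d}" for i in range(params.n_samples)]
    truth = _expand_truth(panel, samples, params.cnv_events)

    groups = rng.integers(0, params.efficiency_groups, size=m)
    lo, hi = params.efficiency_range
    centres = rng.uniform(lo, hi, size=params.efficiency_groups)
    eff = np.clip(centres[groups] + rng.normal(0.0, params.efficiency_spread, size=m),
                  0.05, None)
    depth = np.exp(rng.normal(np.log(params.mean_coverage),
                              params.amplicon_depth_sd, size=m))
    cond = np.exp(rng.normal(0.0, params.sample_condition_sd,
                             size=(params.efficiency_groups, params.n_samples)))

    f = cond[groups, :]                      # (m, n)
    ratio = (1.0 + eff[:, None] * f) / (1.0 + eff[:, None])
    mu = depth[:, None] * ratio ** params.n_cycles
    wild_ok = mu >= 1.0
    if not wild_ok.all():
        bad = np.argwhere(~wild_ok)[0]
        raise ValueError(
            f"wild-type expected coverage below 1 read (amplicon index {bad[0]}, "
            f"sample index {bad[1]}); raise mean_coverage or lower the spreads")
    mu = mu * truth.multipliers.to_numpy()
    if params.overdispersion_sd > 0.0:
        mu = mu * np.exp(rng.normal(0.0, params.overdispersion_sd, size=mu.shape))
    counts = rng.poisson(mu)
    df = pd.DataFrame(counts.astype(np.int64), index=panel.ids, columns=samples)
    truth.amplicon_groups = groups
    return CoverageMatrix(panel, df), truth


def random_events(panel: AmpliconPanel, samples, n_carriers: int,
                  rng: np.random.Generator,
                  multipliers=(0.5, 1.5),
                  min_amplicons: int = 2, max_amplicons: int = 10,
                  max_site_fraction: float = 0.2) -> list[CnvEvent]:
    """Draw one CNV event per carrier: a contiguous run of sites within one
    gene whose amplicon count lies in [min_amplicons, max_amplicons], with a
    uniformly chosen multiplier.  Per-site carrier fraction stays below
    ``max_site_fraction``."""
    site_list = list(panel.sites)
    runs = []
    for start in range(len(site_list)):
        gene = panel.site_gene[site_list[start]]
        total = 0
        for stop in range(start, len(site_list)):
            if panel.site_gene[site_list[stop]] != gene:
                break
            total += len(panel.sites[site_list[stop]])
            if total > max_amplicons:
                break
            if total >= min_amplicons:
                runs.append((gene, tuple(site_list[start:stop + 1])))
    if not runs:
        raise ValueError("panel admits no event of the requested size")
    carriers = rng.choice(list(samples), size=n_carriers, replace=False)
    max_carriers = max(1, int(max_site_fraction * len(list(samples))))
    site_load = dict.fromkeys(site_list, 0)
    events = []
    for sample in carriers:
        for _ in range(100):
            gene, sites = runs[int(rng.integers(len(runs)))]
            if all(site_load[s] < max_carriers for s in sites):
                break
        else:
            raise ValueError("could not place events under the carrier-fraction cap")
        for s in sites:
            site_load[s] += 1
        events.append(CnvEvent(sample=str(sample), gene=gene, sites=sites,
                               multiplier=float(rng.choice(multipliers))))
    return events


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

_STATE_OF_MULT = {0.0: "HOM_DEL", 0.5: "HET_DEL", 1.5: "DUP", 2.0: "DUP"}


def _wilson(k: int, n: int) -> tuple[float, float]:
    from statsmodels.stats.proportion import proportion_confint
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def score_calls(report: pd.DataFrame, truth: TruthSet, panel: AmpliconPanel,
                overlap_fraction: float = 0.5) -> dict:
    """Match called site-runs to true events: a call is a true positive when
    it overlaps at least ``overlap_fraction`` of a true event's amplicon span
    (same sample, same direction).  Duplications confined to a single site
    are excluded from the truth, matching the caller's reporting convention
    (their models overlap the wild-type one too much to be called from one
    exon).

    Note: the metric reported as ``sensitivity`` is the standard
    TP / (TP + FN); a "proportion of true positives among all positive
    results" reading would instead be the precision, reported here as
    ``ppv``.
    """
    amp_index = {a: i for i, a in enumerate(panel.ids)}

    def span(sites) -> set:
        out = set()
        for s in sites:
            out.update(amp_index[a] for a in panel.sites[s])
        return out

    truth_items = []
    excluded = 0
    for ev in truth.events:
        if ev.multiplier >= 1.5 and len(ev.sites) == 1:
            excluded += 1
            continue
        truth_items.append((ev, span(ev.sites), _STATE_OF_MULT[ev.multiplier]))

    calls = []
    if len(report):
        for _, row in report.iterrows():
            idx = set(range(int(row["first_index"]), int(row["last_index"]) + 1))
            calls.append({"sample": row["sample"], "state": row["state"],
                          "span": idx, "n_amplicons": int(row["n_amplicons"]),
                          "matched": False})

    tp = 0
    fn_lengths, tp_lengths = [], []
    for ev, ev_span, state in truth_items:
        hit = False
        for call in calls:
            if call["sample"] != ev.sample or call["matched"]:
                continue
            if call["state"] != state and not (
                    state == "HOM_DEL" and call["state"] in ("HOM_DEL", "HET_DEL")):
                continue
            if len(call["span"] & ev_span) / len(ev_span) >= overlap_fraction:
                call["matched"] = True
                hit = True
                break
        (tp_lengths if hit else fn_lengths).append(len(ev_span))
        tp += hit
    fn = len(truth_items) - tp
    fp_calls = [c for c in calls if not c["matched"]]
    fp = len(fp_calls)

    site_index = {s: i for i, s in enumerate(panel.sites)}
    n_units = len(site_index) * truth.multipliers.shape[1]
    positive_units = set()
    for ev in truth.events:
        for s in ev.sites:
            positive_units.add((ev.sample, site_index[s]))
    fp_units = set()
    for c in fp_calls:
        for i in c["span"]:
            fp_units.add((c["sample"], site_index[panel.site_of(panel.ids[i])]))
    negatives = n_units - len(positive_units)
    tn = negatives - len(fp_units)

    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / negatives if negatives else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    return {
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "excluded_single_site_dups": excluded,
        "sensitivity": sens, "sensitivity_ci": _wilson(tp, tp + fn),
        "specificity": spec, "specificity_ci": _wilson(tn, negatives),
        "ppv": ppv,
        "tp_lengths": sorted(tp_lengths), "fn_lengths": sorted(fn_lengths),
    }


def variance_correction_ratio(rate: float, multiplier: float,
                              n_draws: int, rng: np.random.Generator) -> float:
    """Monte-Carlo ratio Var(log Pois(multiplier * rate)) / Var(log Pois(rate)).

    The supervised caller's deletion and duplication models inflate/deflate
    the wild-type variance by exactly these ratios (2 at multiplier 0.5, 2/3
    at 1.5), which the delta method predicts for log-transformed Poisson
    counts: Var(log X) ~ 1/lambda.
    """
    base = rng.poisson(rate, size=n_draws).astype(float)
    scaled = rng.poisson(multiplier * rate, size=n_draws).astype(float)
    if (base <= 0).any() or (scaled <= 0).any():
        raise ValueError("zero counts drawn; use a larger rate")
    return float(np.var(np.log(scaled), ddof=1) / np.var(np.log(base), ddof=1))
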