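"""Accuracy metrics, stratified reports and the amino-acid-specific
random baseline for torsion-angle prediction.

Three residue-level measures compare predicted with observed angles:

* CC        — Pearson product-moment correlation on the raw angle
              values (no wrap correction; a circular-correlation variant
              is available separately);
* MAE       — mean absolute difference in degrees, by default the
              wrap-aware circular difference (shortest arc, in
              [0, 180]); a linear mode ignoring periodicity is provided;
* RMSE      — root mean square error, on the raw degree scale
              (RMSE_raw) and on the normalized target scale (RMSE_norm).

Reports can be stratified by amino-acid type, three-state secondary
structure, two-state solvent accessibility, 20-degree observed-angle
bins, and per chain (with the cumulative fractions of chains reaching a
given CC).

The null model is an amino-acid-specific random predictor: every test
residue is assigned an angle drawn uniformly from the training-set pool
of angles observed for the same amino-acid type, and the MAE is
averaged over many repeats (default 10,000).  ``expected_random_mae``
gives the exact expectation of that procedure.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import AngleNormalizer, angular_difference, wrap_angle
from .profiles import AngleRecord

logger = logging.getLogger(__name__)

ANGLE_BIN_EDGES = np.arange(-180.0, 181.0, 20.0)  # 18 bins covering [-180, 180)


@dataclass
class MetricSet:
    cc: float
    mae: float
    rmse_raw: float
    rmse_norm: float
    n: int


@dataclass
class StratifiedReport:
    overall: MetricSet
    by_aa: dict[str, MetricSet] = field(default_factory=dict)
    by_ss: dict[str, MetricSet] = field(default_factory=dict)
    by_sa: dict[str, MetricSet] = field(default_factory=dict)
    by_bin: dict[str, MetricSet] = field(default_factory=dict)
    per_chain: dict[str, MetricSet] = field(default_factory=dict)
    chain_summary: dict[str, float] = field(default_factory=dict)


def pearson_cc(observed, predicted) -> float:
    """Pearson correlation on raw angle values.

    Returns NaN with a warning when either vector has zero variance.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance: correlation undefined")
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def circular_cc(observed, predicted) -> float:
    """Jammalamadaka-SenGupta circular correlation (wrap-aware variant;
    not the convention used in the benchmark tables)."""
    x = np.radians(np.asarray(observed, dtype=float))
    y = np.radians(np.asarray(predicted, dtype=float))
    sx = np.sin(x - math.atan2(np.sin(x).sum(), np.cos(x).sum()))
    sy = np.sin(y - math.atan2(np.sin(y).sum(), np.cos(y).sum()))
    denom = math.sqrt((sx ** 2).sum() * (sy ** 2).sum())
    if denom == 0:
        return math.nan
    return float((sx * sy).sum() / denom)


def mae(observed, predicted, mode: str = "circular") -> float:
    """Mean absolute error in degrees."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("need two equal-length non-empty vectors")
    return float(np.mean(angular_difference(x, y, mode)))


def rmse(observed, predicted, mode: str = "circular",
         scale: str = "raw", normalizer: AngleNormalizer | None = None,
         which: str | None = None) -> float:
    """Root mean square error on the raw (degrees) or normalized scale."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("need two equal-length non-empty vectors")
    if scale == "raw":
        d = angular_difference(x, y, mode)
    elif scale == "norm":
        if normalizer is None or which is None:
            raise ValueError("norm scale needs a normalizer and angle type")
        d = normalizer.normalize(x, which) - normalizer.normalize(y, which)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return float(np.sqrt(np.mean(np.square(d))))


def compute_metrics(observed, predicted, mode: str = "circular",
                    normalizer: AngleNormalizer | None = None,
                    which: str | None = None) -> MetricSet:
    """All metrics for one observed/predicted pair of vectors.

    Pairs where either value is undefined (NaN) are excluded first.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n == 0:
        return MetricSet(cc=math.nan, mae=math.nan, rmse_raw=math.nan,
                         rmse_norm=math.nan, n=0)
    cc = pearson_cc(x, y) if n >= 2 else math.nan
    rmse_n = (rmse(x, y, mode, "norm", normalizer, which)
              if normalizer is not None and which is not None else math.nan)
    return MetricSet(cc=cc, mae=mae(x, y, mode),
                     rmse_raw=rmse(x, y, mode, "raw"),
                     rmse_norm=rmse_n, n=n)


def _bin_label(theta: float) -> str:
    w = wrap_angle(theta)
    if w == 180.0:
        w = -180.0
    lo = 20.0 * math.floor(w / 20.0)
    return f"[{lo:.0f},{lo + 20:.0f})"


def evaluate_dataset(per_chain_records: dict[str, list[AngleRecord]],
                     which: str, mode: str = "circular",
                     normalizer: AngleNormalizer | None = None,
                     cc_thresholds: tuple[float, ...] = (0.5, 0.6),
                     ) -> StratifiedReport:
    """Residue- and chain-level stratified evaluation of one angle type.

    The overall and stratified metrics pool residues across chains; the
    chain-level summary reports the mean and median of per-chain metrics
    plus the fraction of chains whose CC reaches each threshold.  Chains
    with fewer than two defined pairs are skipped from the chain-level
    statistics with a warning.
    """
    obs_all, pred_all = [], []
    strata: dict[str, dict[str, tuple[list, list]]] = {
        "aa": {}, "ss": {}, "sa": {}, "bin": {}}
    per_chain: dict[str, MetricSet] = {}

    for chain_id, records in per_chain_records.items():
        obs = np.array([getattr(r, which) for r in records], dtype=float)
        pred = np.array([getattr(r, f"{which}_pred") for r in records],
                        dtype=float)
        keep = np.isfinite(obs) & np.isfinite(pred)
        if keep.sum() < 2:
            logger.warning("chain %s has < 2 defined pairs; skipped from "
                           "chain-level statistics", chain_id)
        else:
            per_chain[chain_id] = compute_metrics(obs[keep], pred[keep], mode,
                                                  normalizer, which)
        for r, o, p, k in zip(records, obs, pred, keep):
            if not k:
                continue
            obs_all.append(o)
            pred_all.append(p)
            for key, label in (("aa", r.residue_name), ("ss", r.ss),
                               ("sa", r.sa), ("bin", _bin_label(o))):
                strata[key].setdefault(label, ([], []))
                strata[key][label][0].append(o)
                strata[key][label][1].append(p)

    overall = compute_metrics(obs_all, pred_all, mode, normalizer, which)
    report = StratifiedReport(overall=overall, per_chain=per_chain)
    for attr, key in (("by_aa", "aa"), ("by_ss", "ss"), ("by_sa", "sa"),
                      ("by_bin", "bin")):
        getattr(report, attr).update({
            label: compute_metrics(o, p, mode, normalizer, which)
            for label, (o, p) in sorted(strata[key].items())})

    if per_chain:
        ccs = np.array([m.cc for m in per_chain.values()])
        maes = np.array([m.mae for m in per_chain.values()])
        finite_cc = ccs[np.isfinite(ccs)]
        report.chain_summary = {
            "n_chains": len(per_chain),
            "mean_cc": float(np.mean(finite_cc)) if finite_cc.size else math.nan,
            "median_cc": float(np.median(finite_cc)) if finite_cc.size else math.nan,
            "mean_mae": float(np.mean(maes)),
            "median_mae": float(np.median(maes)),
            # chain-level RMSE both ways: mean of per-chain RMSEs and pooled
            "mean_chain_rmse_raw": float(np.mean(
                [m.rmse_raw for m in per_chain.values()])),
            "pooled_rmse_raw": overall.rmse_raw,
        }
        for t in cc_thresholds:
            frac = float(np.mean(finite_cc >= t)) if finite_cc.size else math.nan
            report.chain_summary[f"frac_cc_ge_{t:g}"] = frac
    return report


# ---------------------------------------------------------------------------
# amino-acid-specific random baseline
# ---------------------------------------------------------------------------

@dataclass
class RandomBaselineConfig:
    repeats: int = 10000
    seed: int = 0
    granularity: str = "per_aa"  # or "global"

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.granularity not in ("per_aa", "global"):
            raise ValueError(f"unknown granularity {self.granularity!r}")


@dataclass
class BaselineResult:
    mean_mae: float              # mean over repeats of the overall MAE
    se_mae: float                # standard error of that mean
    n_residues: int
    repeats: int
    by_aa: dict[str, float] = field(default_factory=dict)
    by_ss: dict[str, float] = field(default_factory=dict)


def _angle_pools(records: list[AngleRecord], which: str) -> dict[str, np.ndarray]:
    pools: dict[str, list[float]] = {}
    for r in records:
        v = getattr(r, which)
        if math.isfinite(v):
            pools.setdefault(r.residue_name, []).append(v)
    return {aa: np.asarray(v) for aa, v in pools.items()}


def _flatten(records_or_chains) -> list[AngleRecord]:
    if not records_or_chains:
        return []
    first = records_or_chains[0]
    if isinstance(first, AngleRecord):
        return list(records_or_chains)
    return [r for chain in records_or_chains for r in chain]


def random_baseline_mae(training_records, test_records, which: str,
                        config: RandomBaselineConfig = RandomBaselineConfig(),
                        mode: str = "circular",
                        chunk: int = 500) -> BaselineResult:
    """Monte-Carlo amino-acid-specific random predictor.

    Every repeat assigns each test residue an angle drawn uniformly from
    the training pool of its amino-acid type (or from the global pool);
    a test amino acid absent from the training pools falls back to the
    global pool with a warning.  Returns the mean over repeats of the
    overall MAE plus per-amino-acid and per-secondary-structure means.
    """
    train = _flatten(training_records)
    test = _flatten(test_records)
    pools = _angle_pools(train, which)
    global_pool = np.concatenate(list(pools.values())) if pools else np.array([])
    if global_pool.size == 0:
        raise ValueError("empty training angle pool")

    obs, aas, sss = [], [], []
    for r in test:
        v = getattr(r, which)
        if math.isfinite(v):
            obs.append(v)
            aas.append(r.residue_name)
            sss.append(r.ss)
    obs = np.asarray(obs)
    n = obs.size
    if n == 0:
        raise ValueError("no defined test angles")

    res_pools = []
    for aa in aas:
        if config.granularity == "global" or aa not in pools:
            if config.granularity == "per_aa" and aa not in pools:
                logger.warning("amino acid %s absent from training pool; "
                               "using global pool", aa)
            res_pools.append(global_pool)
        else:
            res_pools.append(pools[aa])

    rng = np.random.default_rng(config.seed)
    repeat_maes = np.empty(config.repeats)
    res_sum = np.zeros(n)  # summed diff per residue over all repeats
    done = 0
    pool_sizes = np.array([p.size for p in res_pools])
    while done < config.repeats:
        c = min(chunk, config.repeats - done)
        draw_idx = rng.random((c, n)) * pool_sizes  # uniform per-residue index
        draw_idx = draw_idx.astype(np.int64)
        sampled = np.empty((c, n))
        for j, p in enumerate(res_pools):
            sampled[:, j] = p[draw_idx[:, j]]
        diffs = angular_difference(sampled, obs[None, :], mode)
        repeat_maes[done:done + c] = diffs.mean(axis=1)
        res_sum += diffs.sum(axis=0)
        done += c

    res_mean = res_sum / config.repeats
    by_aa: dict[str, list[float]] = {}
    by_ss: dict[str, list[float]] = {}
    for aa, ss, m in zip(aas, sss, res_mean):
        by_aa.setdefault(aa, []).append(m)
        by_ss.setdefault(ss, []).append(m)
    return BaselineResult(
        mean_mae=float(repeat_maes.mean()),
        se_mae=float(repeat_maes.std(ddof=1) / math.sqrt(config.repeats))
        if config.repeats > 1 else math.nan,
        n_residues=n, repeats=config.repeats,
        by_aa={k: float(np.mean(v)) for k, v in sorted(by_aa.items())},
        by_ss={k: float(np.mean(v)) for k, v in sorted(by_ss.items())})


def expected_random_mae(pool, observed, mode: str = "circular") -> float:
    """Exact expectation of the random-assignment MAE for one pool:
    the average over observations of the mean pool-vs-observation
    angular difference."""
    pool = np.asarray(pool, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if pool.size == 0 or observed.size == 0:
        raise ValueError("pool and observations must be non-empty")
    d = angular_difference(observed[:, None], pool[None, :], mode)
    return float(d.mean(axis=1).mean())


def expected_baseline(training_records, test_records, which: str,
                      mode: str = "circular",
                      granularity: str = "per_aa") -> float:
    """Exact expectation of the amino-acid-specific random baseline over
    a whole test set (the infinite-repeats limit of
    ``random_baseline_mae``)."""
    train = _flatten(training_records)
    test = _flatten(test_records)
    pools = _angle_pools(train, which)
    global_pool = np.concatenate(list(pools.values())) if pools else np.array([])
    if global_pool.size == 0:
        raise ValueError("empty training angle pool")
    per_res = []
    for r in test:
        v = getattr(r, which)
        if not math.isfinite(v):
            continue
        pool = (pools.get(r.residue_name, global_pool)
                if granularity == "per_aa" else global_pool)
        per_res.append(float(np.mean(angular_difference(v, pool, mode))))
    if not per_res:
        raise ValueError("no defined test angles")
    return float(np.mean(per_res))


def wilcoxon_paired(mae_a, mae_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test between paired per-chain MAEs
    (exact null for small n without ties, normal approximation beyond)."""
    from scipy.stats import wilcoxon

    a = np.asarray(mae_a, dtype=float)
    b = np.asarray(mae_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = wilcoxon(a, b, alternative="two-sided",
                       method="exact" if a.size <= 25 else "approx")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def report_frame(report: StratifiedReport, which: str = ""):
    """Stratified report as a tidy DataFrame (one row per stratum)."""
    import pandas as pd

    rows = []

    def add(group, label, m: MetricSet):
        rows.append({"angle": which, "group": group, "stratum": label,
                     "cc": m.cc, "mae": m.mae, "rmse_raw": m.rmse_raw,
                     "rmse_norm": m.rmse_norm, "n": m.n})

    add("overall", "all", report.overall)
    for group, d in (("aa", report.by_aa), ("ss", report.by_ss),
                     ("sa", report.by_sa), ("bin", report.by_bin),
                     ("chain", report.per_chain)):
        for label, m in d.items():
            add(group, label, m)
    return pd.DataFrame(rows)


def write_report(report: StratifiedReport, path, which: str = ""):
    """Write the stratified table (TSV) plus a key-value summary."""
    frame = report_frame(report, which)
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
    summary_path = str(path) + ".summary"
    with open(summary_path, "w") as fh:
        fh.write(f"angle\t{which}\n")
        fh.write(f"overall_cc\t{report.overall.cc:.4f}\n")
        fh.write(f"overall_mae\t{report.overall.mae:.4f}\n")
        fh.write(f"overall_rmse_raw\t{report.overall.rmse_raw:.4f}\n")
        fh.write(f"overall_rmse_norm\t{report.overall.rmse_norm:.4f}\n")
        fh.write(f"overall_n\t{report.overall.n}\n")
        for k, v in report.chain_summary.items():
            fh.write(f"{k}\t{v:.4f}\n" if isinstance(v, float) else f"{k}\t{v}\n")
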