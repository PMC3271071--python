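"""Two-level support vector regression cascade for torsion angles.

A separate cascade is trained per angle type (phi, psi).  The first
level is an epsilon-SVR with an RBF kernel mapping the sliding-window
profile features of a residue to its normalized angle.  The second
level is another epsilon-SVR whose input for a residue is the window of
first-level predictions over its sequence neighbourhood, capturing the
contextual coupling of torsion angles along the chain; its output is
the refined normalized angle, which is then mapped back to degrees and
wrapped onto (-180, 180].

Default hyperparameters (shared by both levels): RBF kernel with
epsilon = 0.01, gamma = 0.01 and C = 5.0.  The default operating point
is scheme PB+PP with window L = 9 for phi and PB+PP+SC with L = 9 for
psi, the combinations with the best benchmark error for each angle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
from sklearn.svm import SVR

from .encoding import (DEFAULT_GLOBAL_WIDTH, WindowConfig,
                       encode_chain_features, scheme_dimension)
from .geometry import AngleNormalizer, fit_normalizer
from .profiles import AA_1TO3, AngleRecord, ProfileBundle

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

DEFAULT_SCHEMES = {"phi": "PB+PP", "psi": "PB+PP+SC"}


class ModelFormatError(RuntimeError):
    """Saved model archive has an incompatible format version."""


@dataclass(frozen=True)
class SvrHyperParams:
    kernel: str = "rbf"
    C: float = 5.0
    epsilon: float = 0.01
    gamma: float = 0.01

    def __post_init__(self):
        if self.C <= 0 or self.epsilon <= 0 or self.gamma <= 0:
            raise ValueError("SVR hyperparameters must be positive")


def _make_svr(params: SvrHyperParams) -> SVR:
    return SVR(kernel=params.kernel, C=params.C, epsilon=params.epsilon,
               gamma=params.gamma, cache_size=500)


@dataclass
class TrainingConfig:
    schemes: dict = field(default_factory=lambda: dict(DEFAULT_SCHEMES))
    l: int = 4                      # level-1 half window (L = 9)
    refine_l: int | None = None     # level-2 half window; None -> same as l
    hyperparams: SvrHyperParams = field(default_factory=SvrHyperParams)
    cap_rows: int = 20000           # subsampling cap for desk-scale training
    seed: int = 0
    angles: tuple[str, ...] = ("phi", "psi")
    extra_trim: int = 0
    span_multiplier: float = 6.0
    global_width: int = DEFAULT_GLOBAL_WIDTH
    oof_folds: int = 0              # >1: out-of-fold level-1 preds for level 2

    def __post_init__(self):
        if self.cap_rows < 1:
            raise ValueError("cap_rows must be >= 1")
        if self.refine_l is None:
            self.refine_l = self.l


@dataclass
class AngleHead:
    """Trained pair of regressors for one angle type."""

    scheme: str
    window: WindowConfig
    refine_window: WindowConfig
    level1: SVR
    level2: SVR


@dataclass
class TangleModel:
    heads: dict[str, AngleHead]
    normalizer: AngleNormalizer
    metadata: dict = field(default_factory=dict)


def train_first_level(X: np.ndarray, y: np.ndarray,
                      params: SvrHyperParams = SvrHyperParams()) -> SVR:
    """Fit the feature -> normalized-angle epsilon-SVR."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    svr = _make_svr(params)
    svr.fit(X, y)
    logger.info("level-1 SVR fitted: %d rows, %d features, %d support vectors",
                X.shape[0], X.shape[1], len(svr.support_))
    return svr


def build_second_level_inputs(level1_predictions: np.ndarray,
                              refine_window: WindowConfig) -> np.ndarray:
    """Contextual windows of level-1 predictions along one chain.

    Row i is the window of L2 = 2*l2 + 1 neighbouring predictions centred
    at residue i, zero-padded at the chain ends.
    """
    p = np.asarray(level1_predictions, dtype=float).ravel()
    l2 = refine_window.l
    padded = np.zeros(p.size + 2 * l2)
    padded[l2:l2 + p.size] = p
    return np.lib.stride_tricks.sliding_window_view(padded, refine_window.full).copy()


def train_second_level(level1_predictions: list[np.ndarray],
                       targets: list[np.ndarray],
                       refine_window: WindowConfig,
                       params: SvrHyperParams = SvrHyperParams(),
                       cap_rows: int | None = None,
                       rng: np.random.Generator | None = None) -> SVR:
    """Fit the refinement epsilon-SVR on contextual windows.

    ``level1_predictions`` holds one array per chain covering every
    residue; ``targets`` holds per-chain normalized target arrays with
    NaN at residues that carry no defined angle.
    """
    xs, ys = [], []
    for preds, y in zip(level1_predictions, targets):
        y = np.asarray(y, dtype=float)
        windows = build_second_level_inputs(preds, refine_window)
        mask = np.isfinite(y)
        xs.append(windows[mask])
        ys.append(y[mask])
    X2 = np.vstack(xs)
    y2 = np.concatenate(ys)
    if cap_rows is not None:
        X2, y2 = _subsample(X2, y2, cap_rows,
                            rng if rng is not None else np.random.default_rng(0))
    if X2.shape[0] < 2:
        raise ValueError("need at least 2 training rows for level 2")
    svr = _make_svr(params)
    svr.fit(X2, y2)
    logger.info("level-2 SVR fitted: %d rows, window %d, %d support vectors",
                X2.shape[0], refine_window.full, len(svr.support_))
    return svr


def _subsample(X: np.ndarray, y: np.ndarray, cap: int,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if X.shape[0] <= cap:
        return X, y
    idx = np.sort(rng.choice(X.shape[0], size=cap, replace=False))
    return X[idx], y[idx]


def _chain_targets(records: list[AngleRecord], which: str,
                   normalizer: AngleNormalizer, extra_trim: int) -> np.ndarray:
    """Normalized targets for every residue of one chain, NaN where the
    angle is undefined or terminally trimmed."""
    obs = np.array([getattr(r, which) for r in records], dtype=float)
    out = np.full(obs.shape, np.nan)
    mask = np.isfinite(obs)
    if extra_trim > 0:
        mask[:extra_trim] = False
        mask[mask.size - extra_trim:] = False
    out[mask] = normalizer.normalize(obs[mask], which)
    return out


def train_tangle(chains: list[tuple[ProfileBundle, list[AngleRecord]]],
                 config: TrainingConfig | None = None) -> TangleModel:
    """Train the full cascade (normalizer, level 1, level 2) per angle.

    ``chains`` pairs each profile bundle with its per-residue records
    carrying observed angles.  Level-2 training inputs are in-sample
    level-1 predictions by default; set ``config.oof_folds > 1`` for
    chain-level out-of-fold predictions instead.
    """
    config = config or TrainingConfig()
    if not chains:
        raise ValueError("no training chains")
    phi_all = [r.phi for _, recs in chains for r in recs]
    psi_all = [r.psi for _, recs in chains for r in recs]
    normalizer = fit_normalizer(phi_all, psi_all, config.span_multiplier)

    heads: dict[str, AngleHead] = {}
    for which in config.angles:
        scheme = config.schemes[which]
        window = WindowConfig(config.l)
        refine_window = WindowConfig(config.refine_l)
        rng = np.random.default_rng(config.seed)

        feats = [encode_chain_features(b, scheme, window, config.global_width)
                 for b, _ in chains]
        targets = [_chain_targets(recs, which, normalizer, config.extra_trim)
                   for _, recs in chains]
        defined = [np.isfinite(t) for t in targets]
        n_def = int(sum(m.sum() for m in defined))
        if n_def == 0:
            raise ValueError(f"no defined {which} targets in training data")

        X1 = np.vstack([F[m] for F, m in zip(feats, defined)])
        y1 = np.concatenate([t[m] for t, m in zip(targets, defined)])
        X1, y1 = _subsample(X1, y1, config.cap_rows, rng)
        level1 = train_first_level(X1, y1, config.hyperparams)

        if config.oof_folds > 1:
            preds = _oof_level1_predictions(feats, targets, config, rng)
        else:
            preds = [level1.predict(F) for F in feats]
        level2 = train_second_level(preds, targets, refine_window,
                                    config.hyperparams,
                                    cap_rows=config.cap_rows, rng=rng)
        heads[which] = AngleHead(scheme=scheme, window=window,
                                 refine_window=refine_window,
                                 level1=level1, level2=level2)

    metadata = {
        "format_version": FORMAT_VERSION,
        "seed": config.seed,
        "extra_trim": config.extra_trim,
        "global_width": config.global_width,
        "cap_rows": config.cap_rows,
        "hyperparams": asdict(config.hyperparams),
        "n_training_chains": len(chains),
        "schemes": {k: h.scheme for k, h in heads.items()},
    }
    return TangleModel(heads=heads, normalizer=normalizer, metadata=metadata)


def _oof_level1_predictions(feats, targets, config, rng):
    """Chain-level K-fold out-of-fold level-1 predictions (leakage-reduced
    inputs for level-2 training)."""
    k = config.oof_folds
    n = len(feats)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    preds: list[np.ndarray | None] = [None] * n
    for fold in folds:
        train_idx = [i for i in range(n) if i not in set(fold.tolist())]
        X = np.vstack([feats[i][np.isfinite(targets[i])] for i in train_idx])
        y = np.concatenate([targets[i][np.isfinite(targets[i])]
                            for i in train_idx])
        X, y = _subsample(X, y, config.cap_rows, rng)
        svr = train_first_level(X, y, config.hyperparams)
        for i in fold:
            preds[i] = svr.predict(feats[i])
    return preds


def predict_tangle(model: TangleModel, bundle: ProfileBundle) -> list[AngleRecord]:
    """Predict (phi, psi) in degrees for every residue of a chain.

    Residues excluded by the terminal rule (first residue's phi, last
    residue's psi, plus any extra trim recorded at training time) carry
    NaN predictions.
    """
    n = len(bundle)
    extra_trim = int(model.metadata.get("extra_trim", 0))
    gw = int(model.metadata.get("global_width", DEFAULT_GLOBAL_WIDTH))
    records = [
        AngleRecord(
            residue_name=AA_1TO3.get(aa, "UNK"),
            chain_name=bundle.sequence.id,
            position=str(i + 1),
            ss=bundle.ss.states[i] if bundle.ss is not None else "C",
            sa=bundle.acc.states[i] if bundle.acc is not None else "E",
            disorder=bundle.diso.labels[i] if bundle.diso is not None else ".")
        for i, aa in enumerate(bundle.sequence.sequence)
    ]
    for which, head in model.heads.items():
        expected = scheme_dimension(head.scheme, head.window.full, gw)
        F = encode_chain_features(bundle, head.scheme, head.window, gw)
        if F.shape[1] != expected:  # pragma: no cover - defensive
            raise ValueError("feature width mismatch with model metadata")
        p1 = head.level1.predict(F)
        X2 = build_second_level_inputs(p1, head.refine_window)
        p2 = head.level2.predict(X2)
        degrees = model.normalizer.denormalize(p2, which)
        mask = np.ones(n, dtype=bool)
        if which == "phi":
            mask[0] = False
        else:
            mask[-1] = False
        if extra_trim > 0:
            mask[:extra_trim] = False
            mask[n - extra_trim:] = False
        for i in range(n):
            setattr(records[i], f"{which}_pred",
                    float(degrees[i]) if mask[i] else math.nan)
            setattr(records[i], f"{which}_norm",
                    float(p2[i]) if mask[i] else math.nan)
    return records


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: TangleModel, path):
    """Serialize the model plus a plain-text metadata sidecar."""
    payload = {"format_version": FORMAT_VERSION, "model": model}
    joblib.dump(payload, path)
    sidecar = str(path) + ".meta"
    nz = model.normalizer
    with open(sidecar, "w") as fh:
        fh.write(f"format_version\t{FORMAT_VERSION}\n")
        for k, v in sorted(model.metadata.items()):
            fh.write(f"{k}\t{v}\n")
        fh.write(f"normalizer\tmu_phi={nz.mu_phi} sigma_phi={nz.sigma_phi} "
                 f"mu_psi={nz.mu_psi} sigma_psi={nz.sigma_psi} "
                 f"span={nz.span_multiplier}\n")
        for which, head in model.heads.items():
            fh.write(f"head_{which}\tscheme={head.scheme} l={head.window.l} "
                     f"refine_l={head.refine_window.l}\n")


def load_model(path) -> TangleModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"model archive format {version} incompatible with "
            f"supported version {FORMAT_VERSION}")
    return payload["model"]
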