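"""Sliding-window feature encoding for per-residue regression.

Each residue is described by the profile rows of a local window of
L = 2l + 1 consecutive residues centred on it, with window positions
falling outside the chain contributing exact zeros.  Track blocks are
concatenated per window position in the fixed order PB (20 PSSM
columns / 10), PP (3 secondary-structure probabilities), SC (2
accessibility indicators), DISO (2 disorder probabilities), so the
per-residue widths of the named schemes are::

    PB             20 L
    PB+PP          23 L
    PB+PP+SC       25 L
    PB+PP+DISO     25 L
    PB+PP+SC+DISO  27 L
    ALL            27 L + G

where G (default 22) appends global sequence features once per vector:
the 20 amino-acid composition fractions, a scaled sequence length and a
scaled molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AngleNormalizer
from .profiles import (RESIDUE_MASS, STANDARD_AAS, AngleRecord, ProfileBundle,
                       SequenceRecord)

__all__ = [
    "TRACK_WIDTHS", "SCHEMES", "DEFAULT_GLOBAL_WIDTH",
    "WindowConfig", "GlobalFeatures",
    "scheme_dimension", "compute_global_features", "encode_chain_features",
    "encode_residue", "encode_chain", "dump_svmlight", "load_svmlight",
]

TRACK_WIDTHS = {"PB": 20, "PP": 3, "SC": 2, "DISO": 2}

SCHEMES: dict[str, tuple[str, ...]] = {
    "PB": ("PB",),
    "PB+PP": ("PB", "PP"),
    "PB+PP+SC": ("PB", "PP", "SC"),
    "PB+PP+DISO": ("PB", "PP", "DISO"),
    "PB+PP+SC+DISO": ("PB", "PP", "SC", "DISO"),
    "ALL": ("PB", "PP", "SC", "DISO"),
}

DEFAULT_GLOBAL_WIDTH = 22  # 20 composition fractions + length + weight

# default scaling constants landing typical proteins in [0, 1]
LENGTH_SCALE = 1000.0
WEIGHT_SCALE = 1.0e5  # Da


class EncodingConfigError(ValueError):
    """Scheme requires a track the bundle does not provide."""


@dataclass(frozen=True)
class WindowConfig:
    """Sliding window of L = 2l + 1 residues (l = half window)."""

    l: int

    def __post_init__(self):
        if self.l < 0:
            raise ValueError("half window must be >= 0")

    @property
    def full(self) -> int:
        return 2 * self.l + 1


def per_residue_width(scheme: str) -> int:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    return sum(TRACK_WIDTHS[t] for t in SCHEMES[scheme])


def scheme_dimension(scheme: str, L: int,
                     global_width: int = DEFAULT_GLOBAL_WIDTH) -> int:
    """Total feature-vector width of ``scheme`` at full window length L."""
    if L < 1 or L % 2 == 0:
        raise ValueError(f"window length must be odd and positive, got {L}")
    dim = per_residue_width(scheme) * L
    if scheme == "ALL":
        dim += global_width
    return dim


@dataclass
class GlobalFeatures:
    """Whole-chain features appended once in the ALL scheme."""

    composition: np.ndarray     # 20 fractions in STANDARD_AAS order
    length_feature: float
    weight_feature: float

    def vector(self) -> np.ndarray:
        return np.concatenate([self.composition,
                               [self.length_feature, self.weight_feature]])


def compute_global_features(seq: SequenceRecord | str,
                            length_scale: float = LENGTH_SCALE,
                            weight_scale: float = WEIGHT_SCALE) -> GlobalFeatures:
    """Amino-acid composition plus scaled length and molecular weight.

    Composition fractions use the full sequence length as denominator but
    only count the 20 standard letters, so X residues lower the total
    below 1.  Length is n / 1000 capped at 1; weight is the summed
    average residue mass divided by 1e5.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if not s:
        raise ValueError("empty sequence")
    n = len(s)
    comp = np.array([s.count(a) / n for a in STANDARD_AAS])
    weight = sum(RESIDUE_MASS.get(a, RESIDUE_MASS["X"]) for a in s)
    return GlobalFeatures(composition=comp,
                          length_feature=min(n / length_scale, 1.0),
                          weight_feature=weight / weight_scale)


def _track_matrix(bundle: ProfileBundle, scheme: str) -> np.ndarray:
    """Per-residue track blocks concatenated, shape (L_seq, width)."""
    blocks = []
    for track in SCHEMES[scheme]:
        if track == "PB":
            if bundle.pssm is None:
                raise EncodingConfigError("scheme requires PSSM track")
            blocks.append(bundle.pssm.normalized)
        elif track == "PP":
            if bundle.ss is None:
                raise EncodingConfigError("scheme requires secondary-structure track")
            blocks.append(bundle.ss.probs)
        elif track == "SC":
            if bundle.acc is None:
                raise EncodingConfigError("scheme requires accessibility track")
            blocks.append(bundle.acc.one_hot)
        elif track == "DISO":
            if bundle.diso is None:
                raise EncodingConfigError("scheme requires disorder track")
            blocks.append(bundle.diso.track)
    return np.hstack(blocks)


def encode_chain_features(bundle: ProfileBundle, scheme: str,
                          window: WindowConfig,
                          global_width: int = DEFAULT_GLOBAL_WIDTH) -> np.ndarray:
    """Feature matrix for every residue of the chain, one row per residue.

    Rows are the flattened window (position-major: all track blocks of
    the leftmost window position first); out-of-chain positions are
    zero-padded.  In the ALL scheme the global feature vector is appended
    to every row.
    """
    tracks = _track_matrix(bundle, scheme)
    n, width = tracks.shape
    l = window.l
    padded = np.zeros((n + 2 * l, width))
    padded[l:l + n] = tracks
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (window.full, width))[:, 0]
    X = windows.reshape(n, window.full * width)
    if scheme == "ALL":
        g = compute_global_features(bundle.sequence).vector()
        if global_width != g.shape[0]:
            raise EncodingConfigError(
                f"configured global width {global_width} != produced "
                f"{g.shape[0]}")
        X = np.hstack([X, np.tile(g, (n, 1))])
    return np.ascontiguousarray(X)


def encode_residue(bundle: ProfileBundle, index: int, scheme: str,
                   window: WindowConfig,
                   global_width: int = DEFAULT_GLOBAL_WIDTH) -> np.ndarray:
    """Feature vector for a single residue (0-based index)."""
    if not 0 <= index < len(bundle):
        raise IndexError(f"residue index {index} outside chain of "
                         f"length {len(bundle)}")
    return encode_chain_features(bundle, scheme, window, global_width)[index]


def encode_chain(bundle: ProfileBundle, scheme: str, window: WindowConfig,
                 targets: list[AngleRecord], which: str,
                 normalizer: AngleNormalizer, extra_trim: int = 0,
                 global_width: int = DEFAULT_GLOBAL_WIDTH,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Training matrix for one chain and one angle type.

    Returns ``(X, y, indices)`` where rows cover exactly the residues
    whose target angle is defined and not excluded by the terminal trim,
    in sequence order; ``y`` holds normalized angles and ``indices`` the
    0-based residue positions of the rows.
    """
    if len(targets) != len(bundle):
        raise ValueError(
            f"targets length {len(targets)} != chain length {len(bundle)}")
    obs = np.array([getattr(t, which) for t in targets], dtype=float)
    mask = np.isfinite(obs)
    if extra_trim > 0:
        mask[:extra_trim] = False
        mask[len(mask) - extra_trim:] = False
    X = encode_chain_features(bundle, scheme, window, global_width)
    idx = np.flatnonzero(mask)
    y = normalizer.normalize(obs[idx], which)
    return X[idx], np.atleast_1d(y), idx


# ---------------------------------------------------------------------------
# SVM-light sparse import/export
# ---------------------------------------------------------------------------

def dump_svmlight(X: np.ndarray, y: np.ndarray, dest):
    """Write a feature matrix in SVM-light sparse format (1-based indices)."""
    from sklearn.datasets import dump_svmlight_file
    dump_svmlight_file(X, y, dest, zero_based=False)


def load_svmlight(source, n_features: int | None = None):
    from sklearn.datasets import load_svmlight_file
    X, y = load_svmlight_file(source, n_features=n_features, zero_based=False)
    return X.toarray(), y
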