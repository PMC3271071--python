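"""Synthetic chain generator for end-to-end testing without downloads.

The generator emulates the statistical structure that makes torsion
angles learnable from sequence profiles: secondary structure arranged
in segments, Ramachandran-basin angle distributions conditioned on the
secondary-structure state and on residue identity (glycine's
sign-symmetric phi, proline's phi locked near -75 degrees), and profile
tracks that are noisy renditions of the underlying truth, written in
exactly the file dialects the profile readers accept.

The default angle basins are design choices mimicking the familiar
Ramachandran picture — a single phi mode near -70 degrees and a bimodal
psi — not measurements: helix phi ~ N(-63, 8), psi ~ N(-42, 10); strand
phi ~ N(-120, 20), psi ~ N(135, 20); coil a broad three-component
mixture.  What the generator does not emulate: real covalent geometry,
long-range tertiary contacts, the correlated errors of actual upstream
predictors, or database-derived PSSM statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import wrap_angle
from .profiles import (AA_1TO3, STANDARD_AAS, AccessibilityProfile,
                       AngleRecord, DisorderProfile, ProfileBundle,
                       PssmProfile, PSSM_ALPHABET, SecondaryStructureProfile,
                       SequenceRecord, read_dataset_dir, write_binary_accessibility,
                       write_chain_angles, write_disorder, write_fasta,
                       write_psipred_ss2, write_pssm)

__all__ = ["SyntheticConfig", "SyntheticChain", "SyntheticDataset",
           "generate_chain", "generate_dataset", "write_fixture_files",
           "read_fixture_dir"]

# angle mixture components per secondary-structure state:
# (weight, mu_phi, sd_phi, mu_psi, sd_psi), degrees
DEFAULT_ANGLE_COMPONENTS = {
    "H": [(1.0, -63.0, 8.0, -42.0, 10.0)],
    "E": [(1.0, -120.0, 20.0, 135.0, 20.0)],
    "C": [(0.45, -75.0, 30.0, 150.0, 40.0),   # PPII / beta basin
          (0.35, -70.0, 25.0, -25.0, 30.0),   # alpha basin
          (0.20, 60.0, 25.0, 45.0, 30.0)],    # left-handed alpha
}

PRO_PHI = (-75.0, 10.0)  # proline phi is nearly locked regardless of state

# amino-acid propensities per secondary-structure state (unnormalized)
_HELIX_FORMERS = "AELKMQRH"
_STRAND_FORMERS = "VIFYTWC"
_COIL_FORMERS = "GPSND"


def _aa_weights(state: str) -> np.ndarray:
    w = np.ones(20)
    favored = {"H": _HELIX_FORMERS, "E": _STRAND_FORMERS,
               "C": _COIL_FORMERS}[state]
    for aa in favored:
        w[STANDARD_AAS.index(aa)] += 2.0
    return w / w.sum()


_HYDROPHOBIC = set("ACFILMVWY")


@dataclass
class SyntheticConfig:
    n_chains: int = 30
    length_range: tuple[int, int] = (50, 120)
    mean_segment: dict = field(default_factory=lambda: {"H": 9.0, "E": 5.0,
                                                        "C": 4.0})
    state_weights: dict = field(default_factory=lambda: {"H": 0.35, "E": 0.25,
                                                         "C": 0.40})
    angle_components: dict = field(
        default_factory=lambda: {k: list(v) for k, v in
                                 DEFAULT_ANGLE_COMPONENTS.items()})
    pssm_signal: float = 7.0     # mean log-odds of the true residue
    pssm_noise: float = 2.0      # SD of log-odds noise
    ss_confusion: float = 0.15   # smear and occasional flip of the SS track
    sa_error: float = 0.10       # label-flip rate of the accessibility track
    diso_noise: float = 0.05     # SD of disorder-probability noise
    gly_phi_flip: float = 0.4    # probability of mirroring glycine's phi
    seed: int = 0

    def __post_init__(self):
        for comps in self.angle_components.values():
            for (_, _, sd_phi, _, sd_psi) in comps:
                if sd_phi <= 0 or sd_psi <= 0:
                    raise ValueError("angle SDs must be positive")
        for rate in (self.ss_confusion, self.sa_error):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class SyntheticChain:
    sequence: SequenceRecord
    ss_true: str
    records: list[AngleRecord]
    bundle: ProfileBundle


@dataclass
class SyntheticDataset:
    chains: list[SyntheticChain] = field(default_factory=list)
    config: SyntheticConfig | None = None

    def as_training_data(self) -> list[tuple[ProfileBundle, list[AngleRecord]]]:
        return [(c.bundle, c.records) for c in self.chains]

    def __len__(self) -> int:
        return len(self.chains)


def _sample_ss_string(length: int, config: SyntheticConfig,
                      rng: np.random.Generator) -> str:
    states = list(config.state_weights)
    weights = np.array([config.state_weights[s] for s in states], dtype=float)
    weights /= weights.sum()
    out: list[str] = []
    prev = None
    while len(out) < length:
        w = weights.copy()
        if prev is not None:  # no immediate repeat: segments stay visible
            w[states.index(prev)] = 0.0
            w /= w.sum()
        state = states[rng.choice(len(states), p=w)]
        seg = max(1, int(rng.poisson(config.mean_segment[state])))
        out.extend(state * seg)
        prev = state
    return "".join(out[:length])


def _sample_angles(aa: str, state: str, config: SyntheticConfig,
                   rng: np.random.Generator) -> tuple[float, float]:
    comps = config.angle_components[state]
    weights = np.array([c[0] for c in comps], dtype=float)
    weights /= weights.sum()
    _, mu_phi, sd_phi, mu_psi, sd_psi = comps[rng.choice(len(comps), p=weights)]
    if aa == "P":
        mu_phi, sd_phi = PRO_PHI
    if aa == "G":
        sd_phi *= 1.5  # glycine: widened, sign-symmetric phi
    phi = rng.normal(mu_phi, sd_phi)
    psi = rng.normal(mu_psi, sd_psi)
    if aa == "G" and rng.random() < config.gly_phi_flip:
        phi = -phi
    return wrap_angle(phi), wrap_angle(psi)


def _one_hot_ss(state: str) -> np.ndarray:
    v = np.zeros(3)
    v["HEC".index(state)] = 1.0
    return v


def generate_chain(config: SyntheticConfig, rng: np.random.Generator,
                   chain_id: str = "chain_0001") -> SyntheticChain:
    """Sample one chain: secondary-structure segments, a state-biased
    sequence, basin-conditioned torsion angles and noisy profile tracks.

    All emitted floating-point tracks are rounded to four decimals so
    that writing and re-reading the text fixture files reproduces the
    dataset exactly.
    """
    lo, hi = config.length_range
    length = int(rng.integers(lo, hi + 1))
    ss = _sample_ss_string(length, config, rng)
    seq_idx = [rng.choice(20, p=_aa_weights(s)) for s in ss]
    seq = "".join(STANDARD_AAS[i] for i in seq_idx)

    phi = np.empty(length)
    psi = np.empty(length)
    for i, (aa, s) in enumerate(zip(seq, ss)):
        phi[i], psi[i] = _sample_angles(aa, s, config, rng)
    phi[0] = math.nan      # terminal angles are geometrically undefined
    psi[-1] = math.nan
    phi = np.round(phi, 4)
    psi = np.round(psi, 4)

    # PSSM: true residue scores high, others low, integer log-odds
    col = {a: PSSM_ALPHABET.index(a) for a in STANDARD_AAS}
    pssm = rng.normal(-2.0, config.pssm_noise, size=(length, 20))
    for i, aa in enumerate(seq):
        pssm[i, col[aa]] = rng.normal(config.pssm_signal, config.pssm_noise)
    pssm = np.round(pssm)

    # secondary-structure probabilities: smeared one-hot, occasional flip
    probs = np.empty((length, 3))
    pred_states = []
    conf = config.ss_confusion
    for i, s in enumerate(ss):
        pred = s
        if conf > 0 and rng.random() < conf / 2:
            pred = rng.choice([t for t in "HEC" if t != s])
        noise = rng.random(3)
        noise /= noise.sum()
        row = (1.0 - conf) * _one_hot_ss(pred) + conf * noise
        probs[i] = np.round(row / row.sum(), 4)
        h, e, c = probs[i]
        pred_states.append("C" if c == max(h, e, c)
                           else ("H" if h >= e else "E"))

    # accessibility: hydrophobics tend buried, with label-flip errors
    acc = []
    for aa in seq:
        p_buried = 0.75 if aa in _HYDROPHOBIC else 0.25
        state = "B" if rng.random() < p_buried else "E"
        if rng.random() < config.sa_error:
            state = "E" if state == "B" else "B"
        acc.append(state)

    # disorder: coil residues near the termini trend disordered
    p_dis = np.empty(length)
    for i, s in enumerate(ss):
        near_term = i < 5 or i >= length - 5
        base = 0.45 if (s == "C" and near_term) else (0.15 if s == "C" else 0.03)
        p_dis[i] = np.clip(base + rng.normal(0, config.diso_noise), 0.0, 1.0)
    p_dis = np.round(p_dis, 4)

    sequence = SequenceRecord(id=chain_id, sequence=seq)
    bundle = ProfileBundle(
        sequence=sequence,
        pssm=PssmProfile(values=pssm, residues=seq),
        ss=SecondaryStructureProfile(probs=probs, states="".join(pred_states),
                                     residues=seq),
        acc=AccessibilityProfile(states="".join(acc)),
        diso=DisorderProfile(p_disordered=p_dis))
    records = [
        AngleRecord(residue_name=AA_1TO3[aa], chain_name=chain_id,
                    position=str(i + 1), phi=phi[i], psi=psi[i],
                    ss=ss[i], sa=acc[i],
                    disorder="*" if p_dis[i] >= 0.5 else ".")
        for i, aa in enumerate(seq)
    ]
    return SyntheticChain(sequence=sequence, ss_true=ss, records=records,
                          bundle=bundle)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate ``config.n_chains`` independent chains, deterministically
    under ``config.seed``, and fill in the normalized-angle columns from
    the dataset's own angle statistics."""
    rng = np.random.default_rng(config.seed)
    chains = [generate_chain(config, rng, chain_id=f"chain_{i + 1:04d}")
              for i in range(config.n_chains)]
    dataset = SyntheticDataset(chains=chains, config=config)
    _fill_normalized(dataset)
    return dataset


def _fill_normalized(dataset: SyntheticDataset):
    from .geometry import fit_normalizer

    records = [r for c in dataset.chains for r in c.records]
    phis = [r.phi for r in records]
    psis = [r.psi for r in records]
    try:
        norm = fit_normalizer(phis, psis)
    except ValueError:
        return
    for r in records:
        if math.isfinite(r.phi):
            r.phi_norm = round(norm.normalize(r.phi, "phi"), 6)
        if math.isfinite(r.psi):
            r.psi_norm = round(norm.normalize(r.psi, "psi"), 6)


def write_fixture_files(dataset: SyntheticDataset, directory) -> list[Path]:
    """Write the dataset as a fixture tree readable by the profile I/O
    layer: one shared FASTA whose headers double as the manifest
    (length and generator seed per chain) plus, per chain, PSSM, ss2,
    accessibility, disorder and angle-table files — 5 files per chain
    plus the FASTA."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    seed = dataset.config.seed if dataset.config else 0
    desc = {c.sequence.id: f"length={len(c.sequence)} seed={seed}"
            for c in dataset.chains}
    fasta = directory / "sequences.fasta"
    write_fasta([c.sequence for c in dataset.chains], fasta, description=desc)
    paths.append(fasta)
    for c in dataset.chains:
        cid = c.sequence.id
        b = c.bundle
        for suffix, writer, payload in (
                (".pssm", write_pssm, b.pssm),
                (".ss2", write_psipred_ss2, b.ss),
                (".acc", write_binary_accessibility, b.acc),
                (".ang", write_chain_angles, c.records)):
            p = directory / f"{cid}{suffix}"
            writer(payload, p)
            paths.append(p)
        p = directory / f"{cid}.diso"
        write_disorder(b.diso, p, residues=c.sequence.sequence)
        paths.append(p)
    return paths


def read_fixture_dir(directory) -> list[tuple[ProfileBundle, list[AngleRecord]]]:
    """Load a fixture tree written by :func:`write_fixture_files`."""
    return read_dataset_dir(directory)
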