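"""Readers and writers for per-residue sequence profile tracks.

Four upstream per-residue tracks feed the torsion-angle predictor, each
in the text dialect of the tool that produces it in practice:

* PSSM      — PSI-BLAST ASCII position-specific scoring matrix (``-Q``),
              20 log-odds columns per residue, divided by 10 so that most
              values fall in [0, 1];
* PP        — PSIPRED ``.ss2`` three-state secondary-structure
              probabilities (helix / strand / coil);
* SC        — two-state solvent accessibility (exposed / buried), one-hot;
* DISO      — per-residue probability of native disorder.

Per-residue angle tables use an 8-column tab-separated dialect: residue
name, chain name, position, observed angle, normalized angle, secondary
structure, accessibility and disorder labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"
# column order of PSI-BLAST PSSM files
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}

# average residue (in-chain monomer) masses, Da
RESIDUE_MASS = {
    "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
    "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
    "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
    "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
    "X": 110.0,
}


class ProfileFormatError(ValueError):
    """Malformed or internally inconsistent profile file."""


def _as_handle(source, mode: str = "r"):
    """Return (handle, needs_close) from a path or an open text handle."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def clean_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase and map non-standard letters to X (with a warning)."""
    seq = seq.upper()
    cleaned = []
    replaced = 0
    for ch in seq:
        if ch in STANDARD_AAS or ch == "X":
            cleaned.append(ch)
        else:
            cleaned.append("X")
            replaced += 1
    if replaced:
        logger.warning("sequence %s: %d non-standard letters mapped to X",
                       record_id, replaced)
    return "".join(cleaned)


def read_fasta(source) -> list[SequenceRecord]:
    """Parse FASTA records; non-standard letters become X."""
    from Bio import SeqIO

    handle, close = _as_handle(source)
    try:
        records = [
            SequenceRecord(id=rec.id, sequence=clean_sequence(str(rec.seq), rec.id))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if close:
            handle.close()
    if not records:
        raise ProfileFormatError("no FASTA records found")
    for rec in records:
        if not rec.sequence:
            raise ProfileFormatError(f"FASTA record {rec.id!r} has empty sequence")
    return records


def write_fasta(records: Iterable[SequenceRecord], dest, description: dict | None = None):
    handle, close = _as_handle(dest, "w")
    try:
        for rec in records:
            desc = ""
            if description and rec.id in description:
                desc = " " + description[rec.id]
            handle.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), 60):
                handle.write(rec.sequence[i:i + 60] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

@dataclass
class PssmProfile:
    """PSI-BLAST log-odds matrix, one row per residue, 20 score columns."""

    values: np.ndarray                 # (L, 20) raw log-odds
    residues: str = ""                 # one-letter sequence from the file
    alphabet: str = PSSM_ALPHABET      # column order

    @property
    def normalized(self) -> np.ndarray:
        """Scores divided by 10 (no clamping); most values land in [0, 1]."""
        return self.values / 10.0

    def __len__(self) -> int:
        return self.values.shape[0]


def read_pssm(source, seq_length: int | None = None) -> PssmProfile:
    """Read a PSI-BLAST ASCII PSSM.

    Data rows carry a residue index, a letter, 20 log-odds scores, 20
    weighted percentages and 2 trailing statistics; only the first 20
    numeric columns are kept.
    """
    handle, close = _as_handle(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()
    rows: list[list[float]] = []
    letters: list[str] = []
    alphabet = PSSM_ALPHABET
    for lineno, line in enumerate(lines, 1):
        tokens = line.split()
        if not tokens:
            continue
        # header row listing the 20 column letters (possibly twice)
        if all(len(t) == 1 and t.isalpha() for t in tokens) and len(tokens) >= 20:
            alphabet = "".join(tokens[:20])
            continue
        if tokens[0].isdigit() and len(tokens) >= 22 and len(tokens[1]) == 1 \
                and tokens[1].isalpha():
            try:
                scores = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise ProfileFormatError(
                    f"PSSM line {lineno}: non-numeric score cell ({exc})") from None
            rows.append(scores)
            letters.append(tokens[1].upper())
    if not rows:
        raise ProfileFormatError("no PSSM data rows found")
    values = np.asarray(rows, dtype=float)
    if seq_length is not None and values.shape[0] != seq_length:
        raise ProfileFormatError(
            f"PSSM has {values.shape[0]} rows, expected {seq_length}")
    return PssmProfile(values=values, residues="".join(letters), alphabet=alphabet)


def write_pssm(profile: PssmProfile, dest):
    """Write a PSI-BLAST-style ASCII PSSM (percentage block zero-filled)."""
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("\nLast position-specific scoring matrix computed\n")
        letters = " ".join(profile.alphabet)
        handle.write("          " + letters + "  " + letters + "\n")
        seq = profile.residues or "X" * len(profile)
        for i, row in enumerate(profile.values):
            scores = " ".join(f"{int(round(v)):3d}" if float(v).is_integer()
                              else f"{v:6.2f}" for v in row)
            pct = " ".join("0" for _ in range(20))
            handle.write(f"{i + 1:5d} {seq[i]}  {scores}  {pct}  1.00 0.50\n")
        handle.write("\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# secondary structure (.ss2)
# ---------------------------------------------------------------------------

SS_STATES = "HEC"


@dataclass
class SecondaryStructureProfile:
    """Three-state secondary-structure probabilities, columns (H, E, C)."""

    probs: np.ndarray          # (L, 3) in internal order H, E, C
    states: str                # per-residue predicted state letters
    residues: str = ""

    def __len__(self) -> int:
        return self.probs.shape[0]


def argmax_state(prob_row) -> str:
    """State with the largest probability; ties resolve to coil."""
    h, e, c = prob_row
    m = max(h, e, c)
    if c == m:
        return "C"
    return "H" if h == m else "E"


def read_psipred_ss2(source) -> SecondaryStructureProfile:
    """Read a PSIPRED ``.ss2`` file: rows ``idx letter state pC pH pE``."""
    handle, close = _as_handle(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()
    probs: list[list[float]] = []
    states: list[str] = []
    letters: list[str] = []
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) < 6:
            raise ProfileFormatError(
                f"ss2 line {lineno}: expected 6 columns, got {len(tokens)}")
        idx, letter, state = tokens[0], tokens[1], tokens[2]
        if not state.isalpha():
            raise ProfileFormatError(f"ss2 line {lineno}: missing state column")
        try:
            p_c, p_h, p_e = (float(t) for t in tokens[3:6])
        except ValueError:
            raise ProfileFormatError(
                f"ss2 line {lineno}: non-numeric probability") from None
        for p in (p_c, p_h, p_e):
            if not 0.0 <= p <= 1.0:
                raise ProfileFormatError(
                    f"ss2 line {lineno}: probability {p} outside [0, 1]")
        probs.append([p_h, p_e, p_c])  # reorder to internal (H, E, C)
        state_u = state.upper()
        states.append(state_u if state_u in "HE" else "C")
        letters.append(letter)
    if not probs:
        raise ProfileFormatError("no ss2 data rows found")
    return SecondaryStructureProfile(probs=np.asarray(probs, dtype=float),
                                     states="".join(states),
                                     residues="".join(letters))


def write_psipred_ss2(profile: SecondaryStructureProfile, dest):
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("# PSIPRED VFORMAT (synthetic profile)\n\n")
        seq = profile.residues or "X" * len(profile)
        for i, (row, state) in enumerate(zip(profile.probs, profile.states)):
            p_h, p_e, p_c = row
            handle.write(f"{i + 1:4d} {seq[i]} {state} "
                         f"{p_c:6.4f} {p_h:6.4f} {p_e:6.4f}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------

@dataclass
class AccessibilityProfile:
    """Two-state (exposed / buried) accessibility labels."""

    states: str  # per-residue 'E' (exposed) or 'B' (buried)

    @property
    def one_hot(self) -> np.ndarray:
        """(L, 2) indicator columns ordered (exposed, buried)."""
        arr = np.zeros((len(self.states), 2))
        for i, s in enumerate(self.states):
            arr[i, 0 if s == "E" else 1] = 1.0
        return arr

    def __len__(self) -> int:
        return len(self.states)


def read_binary_accessibility(source) -> AccessibilityProfile:
    """Read two-state accessibility: either a concatenated letter string
    (``eebb...``, possibly line-wrapped) or a per-line table whose last
    alphabetic token is the state letter."""
    handle, close = _as_handle(source)
    try:
        lines = [ln.strip() for ln in handle.read().splitlines()]
    finally:
        if close:
            handle.close()
    lines = [ln for ln in lines if ln and not ln.startswith(("#", ">"))]
    if not lines:
        raise ProfileFormatError("empty accessibility file")
    states: list[str] = []
    table = any(len(ln.split()) > 1 for ln in lines)
    if table:
        for lineno, ln in enumerate(lines, 1):
            letter_tokens = [t for t in ln.split() if len(t) == 1 and t.isalpha()]
            if not letter_tokens:
                raise ProfileFormatError(
                    f"accessibility line {lineno}: no state letter")
            states.append(letter_tokens[-1])
    else:
        states = list("".join(lines))
    out = []
    for i, s in enumerate(states):
        u = s.upper()
        if u not in "EB":
            raise ProfileFormatError(
                f"accessibility residue {i + 1}: unknown state {s!r}")
        out.append(u)
    return AccessibilityProfile(states="".join(out))


def write_binary_accessibility(profile: AccessibilityProfile, dest):
    handle, close = _as_handle(dest, "w")
    try:
        s = profile.states.lower()
        for i in range(0, len(s), 60):
            handle.write(s[i:i + 60] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# disorder
# ---------------------------------------------------------------------------

@dataclass
class DisorderProfile:
    """Per-residue probability of native disorder (and its complement)."""

    p_disordered: np.ndarray
    p_ordered: np.ndarray | None = None

    def __post_init__(self):
        self.p_disordered = np.asarray(self.p_disordered, dtype=float)
        if self.p_ordered is None:
            self.p_ordered = 1.0 - self.p_disordered
        else:
            self.p_ordered = np.asarray(self.p_ordered, dtype=float)
        for arr, name in ((self.p_disordered, "p_disordered"),
                          (self.p_ordered, "p_ordered")):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ProfileFormatError(f"{name} outside [0, 1]")

    @property
    def track(self) -> np.ndarray:
        """(L, 2) columns ordered (disordered, ordered)."""
        return np.column_stack([self.p_disordered, self.p_ordered])

    @property
    def labels(self) -> str:
        """'*' for predicted disordered (p >= 0.5), '.' otherwise."""
        return "".join("*" if p >= 0.5 else "." for p in self.p_disordered)

    def __len__(self) -> int:
        return self.p_disordered.shape[0]


def read_disorder(source) -> DisorderProfile:
    """Read per-line disorder output; the probability is taken as the last
    numeric token of each data row (the common layout is
    ``idx letter mark probability`` with mark '*' = disordered)."""
    handle, close = _as_handle(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()
    probs: list[float] = []
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        numeric = []
        for tok in stripped.split():
            try:
                numeric.append(float(tok))
            except ValueError:
                pass
        if not numeric:
            raise ProfileFormatError(
                f"disorder line {lineno}: no probability column")
        probs.append(numeric[-1])
    if not probs:
        raise ProfileFormatError("empty disorder file")
    return DisorderProfile(p_disordered=np.asarray(probs))


def write_disorder(profile: DisorderProfile, dest, residues: str = ""):
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("# residue disorder probabilities\n")
        seq = residues or "X" * len(profile)
        for i, p in enumerate(profile.p_disordered):
            mark = "*" if p >= 0.5 else "."
            handle.write(f"{i + 1:5d} {seq[i]} {mark} {p:6.4f}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# profile bundle
# ---------------------------------------------------------------------------

@dataclass
class ProfileBundle:
    """All per-residue tracks for one chain, length-aligned to the sequence."""

    sequence: SequenceRecord
    pssm: PssmProfile | None = None
    ss: SecondaryStructureProfile | None = None
    acc: AccessibilityProfile | None = None
    diso: DisorderProfile | None = None

    def __post_init__(self):
        n = len(self.sequence)
        for name in ("pssm", "ss", "acc", "diso"):
            track = getattr(self, name)
            if track is not None and len(track) != n:
                raise ProfileFormatError(
                    f"track {name} length {len(track)} != sequence length {n} "
                    f"for {self.sequence.id}")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# angle tables
# ---------------------------------------------------------------------------

@dataclass
class AngleTableRow:
    """One row of the 8-column per-residue angle table dialect."""

    residue_name: str
    chain_name: str
    pdb_position: str
    observed_angle: float       # degrees, NaN when undefined
    normalized_angle: float     # unitless, NaN when undefined
    ss_label: str
    sa_label: str
    disorder_label: str


def _fmt_angle(v: float, digits: int = 4) -> str:
    return "NA" if not math.isfinite(v) else f"{v:.{digits}f}"


def _parse_angle(tok: str, lineno: int) -> float:
    if tok in ("NA", "nan", "NaN"):
        return math.nan
    try:
        return float(tok)
    except ValueError:
        raise ProfileFormatError(
            f"angle table line {lineno}: bad numeric field {tok!r}") from None


def read_angle_table(source) -> list[AngleTableRow]:
    handle, close = _as_handle(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()
    rows: list[AngleTableRow] = []
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) != 8:
            raise ProfileFormatError(
                f"angle table line {lineno}: expected 8 columns, "
                f"got {len(tokens)}")
        rows.append(AngleTableRow(
            residue_name=tokens[0], chain_name=tokens[1], pdb_position=tokens[2],
            observed_angle=_parse_angle(tokens[3], lineno),
            normalized_angle=_parse_angle(tokens[4], lineno),
            ss_label=tokens[5], sa_label=tokens[6], disorder_label=tokens[7]))
    return rows


def write_angle_table(rows: Iterable[AngleTableRow], dest):
    handle, close = _as_handle(dest, "w")
    try:
        for r in rows:
            handle.write("\t".join([
                r.residue_name, r.chain_name, str(r.pdb_position),
                _fmt_angle(r.observed_angle), _fmt_angle(r.normalized_angle, 6),
                r.ss_label, r.sa_label, r.disorder_label]) + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# per-residue records combining both angles
# ---------------------------------------------------------------------------

@dataclass
class AngleRecord:
    """Observed / normalized / predicted phi and psi for one residue, with
    its stratification labels (NaN marks an undefined angle)."""

    residue_name: str
    chain_name: str
    position: str
    phi: float = math.nan
    psi: float = math.nan
    phi_norm: float = math.nan
    psi_norm: float = math.nan
    phi_pred: float = math.nan
    psi_pred: float = math.nan
    ss: str = "C"
    sa: str = "E"
    disorder: str = "."


def records_to_table(records: Iterable[AngleRecord], which: str) -> list[AngleTableRow]:
    rows = []
    for r in records:
        rows.append(AngleTableRow(
            residue_name=r.residue_name, chain_name=r.chain_name,
            pdb_position=str(r.position),
            observed_angle=getattr(r, which),
            normalized_angle=getattr(r, f"{which}_norm"),
            ss_label=r.ss, sa_label=r.sa, disorder_label=r.disorder))
    return rows


def table_to_records(phi_rows: list[AngleTableRow],
                     psi_rows: list[AngleTableRow]) -> list[AngleRecord]:
    """Zip aligned phi and psi tables into combined per-residue records."""
    if len(phi_rows) != len(psi_rows):
        raise ProfileFormatError(
            f"phi table has {len(phi_rows)} rows but psi table has "
            f"{len(psi_rows)}")
    records = []
    for p, s in zip(phi_rows, psi_rows):
        if (p.residue_name, p.chain_name, p.pdb_position) != \
                (s.residue_name, s.chain_name, s.pdb_position):
            raise ProfileFormatError(
                f"phi/psi tables disagree at position {p.pdb_position}")
        records.append(AngleRecord(
            residue_name=p.residue_name, chain_name=p.chain_name,
            position=p.pdb_position, phi=p.observed_angle, psi=s.observed_angle,
            phi_norm=p.normalized_angle, psi_norm=s.normalized_angle,
            ss=p.ss_label, sa=p.sa_label, disorder=p.disorder_label))
    return records


def write_chain_angles(records: Iterable[AngleRecord], dest):
    """Write one chain's records as a phi block then a psi block, each in
    the 8-column table dialect."""
    records = list(records)
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("# phi\n")
        write_angle_table(records_to_table(records, "phi"), handle)
        handle.write("# psi\n")
        write_angle_table(records_to_table(records, "psi"), handle)
    finally:
        if close:
            handle.close()


def read_chain_angles(source) -> list[AngleRecord]:
    handle, close = _as_handle(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    blocks: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            name = stripped.lstrip("#").strip().lower()
            if name in ("phi", "psi"):
                current = name
                blocks[current] = []
            continue
        if current is not None and stripped:
            blocks[current].append(line)
    if "phi" not in blocks or "psi" not in blocks:
        raise ProfileFormatError("chain angle file must contain '# phi' and "
                                 "'# psi' blocks")
    import io
    phi_rows = read_angle_table(io.StringIO("\n".join(blocks["phi"])))
    psi_rows = read_angle_table(io.StringIO("\n".join(blocks["psi"])))
    return table_to_records(phi_rows, psi_rows)


# ---------------------------------------------------------------------------
# dataset directories
# ---------------------------------------------------------------------------

def read_dataset_dir(directory) -> list[tuple[ProfileBundle, list[AngleRecord]]]:
    """Load a fixture/data directory: ``sequences.fasta`` plus per-chain
    ``<id>.pssm / .ss2 / .acc / .diso`` and optional ``<id>.ang`` files."""
    directory = Path(directory)
    fasta = directory / "sequences.fasta"
    if not fasta.exists():
        raise FileNotFoundError(f"no sequences.fasta in {directory}")
    dataset = []
    for seq in read_fasta(fasta):
        cid = seq.id
        bundle = ProfileBundle(
            sequence=seq,
            pssm=read_pssm(directory / f"{cid}.pssm", seq_length=len(seq)),
            ss=read_psipred_ss2(directory / f"{cid}.ss2"),
            acc=read_binary_accessibility(directory / f"{cid}.acc"),
            diso=read_disorder(directory / f"{cid}.diso"))
        ang_path = directory / f"{cid}.ang"
        records = read_chain_angles(ang_path) if ang_path.exists() else []
        if records and len(records) != len(seq):
            raise ProfileFormatError(
                f"angle table for {cid} has {len(records)} rows, sequence "
                f"has {len(seq)}")
        dataset.append((bundle, records))
    return dataset
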