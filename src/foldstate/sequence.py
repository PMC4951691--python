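"""Sequence-derived disorder indicators.

Composition statistics (order- vs disorder-promoting residue fractions,
proline content), theoretical average molecular mass, and the
charge-hydropathy (Uversky-plot) classification that separates natively
folded from natively unfolded proteins.

The order-promoting set {I, C, L, V, W, Y, F} and the disorder-promoting set
{A, G, R, D, H, Q, T, K, N, M, S, E, P} partition the 20-letter alphabet, so
their fractions always sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils import ProtParamData

from .config import default_config

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
ORDER_PROMOTING = set("ICLVWYF")
DISORDER_PROMOTING = set("AGRDHQTKNMSEP")


class NonCanonicalResidueError(ValueError):
    """A sequence contains a character outside the 20 canonical codes."""


@dataclass(frozen=True)
class SequenceRecord:
    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.identifier!r}: empty sequence")
        for i, ch in enumerate(self.residues):
            if ch not in CANONICAL:
                raise NonCanonicalResidueError(
                    f"{self.identifier!r}: non-canonical residue {ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class CompositionProfile:
    length: int
    per_residue_fraction: dict[str, float]
    order_fraction: float
    disorder_fraction: float
    proline_fraction: float
    molecular_mass: float          # Da, average masses, one water included
    mean_net_charge: float | None = None       # <R>, absolute net charge per residue
    mean_hydrophobicity: float | None = None   # <H>, rescaled Kyte-Doolittle in [0, 1]
    identifier: str = ""
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "identifier": self.identifier,
            "length": self.length,
            "per_residue_fraction": self.per_residue_fraction,
            "order_fraction": self.order_fraction,
            "disorder_fraction": self.disorder_fraction,
            "proline_fraction": self.proline_fraction,
            "molecular_mass_da": self.molecular_mass,
            "mean_net_charge": self.mean_net_charge,
            "mean_hydrophobicity": self.mean_hydrophobicity,
        }


def read_fasta(path: str | Path, strict: bool = True) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into :class:`SequenceRecord` objects.

    Residues are upper-cased.  In strict mode a non-canonical residue raises
    :class:`NonCanonicalResidueError` naming the position; in lenient mode the
    offending characters are dropped with a warning.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        bad = [(i, ch) for i, ch in enumerate(seq) if ch not in CANONICAL]
        if bad and strict:
            i, ch = bad[0]
            raise NonCanonicalResidueError(
                f"{entry.id!r}: non-canonical residue {ch!r} at position {i + 1}"
            )
        if bad:
            warnings.warn(
                f"{entry.id!r}: dropped {len(bad)} non-canonical residue(s)",
                stacklevel=2,
            )
            seq = "".join(ch for ch in seq if ch in CANONICAL)
        records.append(SequenceRecord(entry.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def composition_profile(
    seq: SequenceRecord,
    pH: float = 7.0,
    window: int = 5,
) -> CompositionProfile:
    """Full composition profile of a sequence, including <R> and <H>.

    Molecular mass uses average (not monoisotopic) residue masses plus one
    water, matching the convention of standard protein-parameter calculators.
    """
    n = len(seq)
    counts: dict[str, int] = {}
    for ch in seq.residues:
        counts[ch] = counts.get(ch, 0) + 1
    per_frac = {aa: counts.get(aa, 0) / n for aa in sorted(CANONICAL)}
    order = sum(counts.get(aa, 0) for aa in ORDER_PROMOTING) / n
    disorder = sum(counts.get(aa, 0) for aa in DISORDER_PROMOTING) / n
    mass = ProteinAnalysis(seq.residues).molecular_weight()
    profile = CompositionProfile(
        length=n,
        per_residue_fraction=per_frac,
        order_fraction=order,
        disorder_fraction=disorder,
        proline_fraction=counts.get("P", 0) / n,
        molecular_mass=mass,
        identifier=seq.identifier,
    )
    profile.mean_net_charge = mean_net_charge(seq, pH=pH)
    if n >= window:
        profile.mean_hydrophobicity = mean_hydrophobicity(seq, window=window)
    return profile


def mean_net_charge(seq: SequenceRecord, pH: float = 7.0) -> float:
    """Mean absolute net charge per residue, <R>.

    At pH 7 the classic charge-hydropathy counting convention is used:
    |#(K, R) - #(D, E)| / N, ignoring histidine and the termini.  At any
    other pH a Henderson-Hasselbalch per-residue model with the configured
    pKa table (side chains D, E, C, Y, H, K, R plus both termini) is used.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    n = len(seq)
    if pH == 7.0:
        pos = sum(seq.residues.count(aa) for aa in "KR")
        neg = sum(seq.residues.count(aa) for aa in "DE")
        return abs(pos - neg) / n
    pka = default_config()["charge_hydropathy"]["pka"]
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - pH))
    for aa in "KRH":
        charge += seq.residues.count(aa) / (1.0 + 10.0 ** (pH - pka[aa]))
    for aa in "DECY":
        charge -= seq.residues.count(aa) / (1.0 + 10.0 ** (pka[aa] - pH))
    return abs(charge) / n


def mean_hydrophobicity(seq: SequenceRecord, window: int = 5) -> float:
    """Mean scaled hydropathy, <H>.

    Kyte-Doolittle values rescaled to [0, 1] by (v + 4.5)/9, averaged over
    every sliding window of the stated width, then averaged over windows —
    the canonical charge-hydropathy plot recipe.
    """
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    scaled = [(ProtParamData.kd[ch] + 4.5) / 9.0 for ch in seq.residues]
    window_means = [
        sum(scaled[i : i + window]) / window for i in range(n - window + 1)
    ]
    return sum(window_means) / len(window_means)


def ch_classify(
    profile: CompositionProfile, config: dict | None = None
) -> tuple[str, float]:
    """Place a profile on the charge-hydropathy plane.

    The boundary line is <R>_b = c1*<H> - c0; points below it (lower mean
    net charge than the boundary at their hydropathy) are ``native_side``.
    Returns the side label and the signed distance <R> - <R>_b (negative on
    the native side).  A point exactly on the boundary is native_side so the
    classification is total.
    """
    cfg = (config or default_config())["charge_hydropathy"]
    if profile.mean_hydrophobicity is None or profile.mean_net_charge is None:
        raise ValueError("profile must have mean_net_charge and mean_hydrophobicity")
    boundary = cfg["c1"] * profile.mean_hydrophobicity - cfg["c0"]
    distance = profile.mean_net_charge - boundary
    side = "native_side" if distance <= 0 else "unfolded_side"
    return side, distance
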