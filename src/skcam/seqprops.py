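"""Sequence-derived physical properties of the protein constructs.

Average molar mass, aromatic and phenylalanine-based extinction coefficients,
and Beer–Lambert concentration determination with the 330–350 nm baseline
convention used for all UV measurements in this pipeline.  Mass and
residue-count arithmetic is delegated to Biopython's ProtParam tables
(standard average residue masses; ε per Trp 5500, per Tyr 1490 M⁻¹cm⁻¹).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = [
    "STANDARD_AA",
    "ProteinSequence",
    "ExtinctionSpec",
    "average_molar_mass",
    "merge_by_overlap",
    "extinction_coefficient_aromatic",
    "extinction_coefficient_from_counts",
    "extinction_coefficient_phe",
    "concentration_from_absorbance",
    "read_fasta",
    "write_fasta",
    "property_record",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: per-residue molar extinction coefficients at 280 nm, M-1 cm-1
EPS_TRP_280 = 5500.0
EPS_TYR_280 = 1490.0

#: wavelength window averaged to estimate the scatter baseline of a UV spectrum
BASELINE_WINDOW_NM = (330.0, 350.0)


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence in one-letter codes.

    ``initiator_met_present`` records whether the leading residue is the
    expression-initiator methionine (position M0 in the construct numbering),
    which is cleaved in mature full-length CaM but retained in the purified
    half- and double-lobe constructs.
    """

    name: str
    residues: str
    initiator_met_present: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(
                f"{self.name}: non-standard residue codes {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def count(self, residue: str) -> int:
        return self.residues.count(residue)


@dataclass(frozen=True)
class ExtinctionSpec:
    """A molar extinction coefficient at a stated wavelength."""

    epsilon: float  # M-1 cm-1
    wavelength: float  # nm
    method: str  # trp_tyr_280 | phe_258 | user_supplied

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 200.0 <= self.wavelength <= 400.0:
            raise ValueError("wavelength outside 200-400 nm")


def average_molar_mass(seq: ProteinSequence, remove_initiator_met: bool = False) -> float:
    """Average (isotope-abundance-weighted) molar mass of the chain, in kDa.

    Sum of standard average residue masses plus one water.  With
    ``remove_initiator_met`` the leading Met (which must be present) is
    excluded, modelling post-translational cleavage.
    """
    residues = seq.residues
    if remove_initiator_met:
        if residues[0] != "M":
            raise ValueError(f"{seq.name}: first residue is not Met")
        residues = residues[1:]
        if not residues:
            raise ValueError(f"{seq.name}: nothing left after Met removal")
    return ProteinAnalysis(residues).molecular_weight() / 1000.0


def merge_by_overlap(
    seqA: ProteinSequence, seqB: ProteinSequence, min_overlap: int = 3
) -> ProteinSequence:
    """Concatenate two sequences over their longest exact suffix/prefix overlap.

    Used to reconstruct full-length CaM from the two printed half-CaM
    sequences, which share the linker segment MKDTD.  The overlap region is
    counted once; the longest exact overlap of length >= ``min_overlap`` wins.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    best = 0
    limit = min(len(seqA), len(seqB))
    for k in range(limit, min_overlap - 1, -1):
        if seqA.residues[-k:] == seqB.residues[:k]:
            best = k
            break
    if best == 0:
        raise ValueError(
            f"no exact overlap of length >= {min_overlap} between "
            f"{seqA.name} and {seqB.name}"
        )
    merged = seqA.residues + seqB.residues[best:]
    return ProteinSequence(
        name=f"{seqA.name}+{seqB.name}",
        residues=merged,
        initiator_met_present=seqA.initiator_met_present,
    )


def extinction_coefficient_aromatic(seq: ProteinSequence) -> ExtinctionSpec:
    """Predicted ε at 280 nm from Trp/Tyr counts (5500/1490 per residue).

    No cystine term: none of the constructs handled here contains cysteine.
    """
    return extinction_coefficient_from_counts(
        n_trp=seq.count("W"), n_tyr=seq.count("Y")
    )


def extinction_coefficient_from_counts(n_trp: int, n_tyr: int) -> ExtinctionSpec:
    """ε280 from aromatic residue counts alone (for composition-only inputs)."""
    if n_trp < 0 or n_tyr < 0:
        raise ValueError("residue counts must be >= 0")
    eps = EPS_TRP_280 * n_trp + EPS_TYR_280 * n_tyr
    return ExtinctionSpec(epsilon=eps, wavelength=280.0, method="trp_tyr_280")


def extinction_coefficient_phe(seq: ProteinSequence, eps_phe: float) -> ExtinctionSpec:
    """ε at 258 nm assuming a linear relation in the number of phenylalanines.

    ``eps_phe`` is the measured molar extinction of free L-phenylalanine at
    its 258-nm maximum.
    """
    if eps_phe <= 0:
        raise ValueError("eps_phe must be > 0")
    return ExtinctionSpec(
        epsilon=seq.count("F") * eps_phe, wavelength=258.0, method="phe_258"
    )


def concentration_from_absorbance(
    spectrum: Mapping[float, float],
    ext: ExtinctionSpec,
    path_length_cm: float = 1.0,
) -> float:
    """Molar concentration from a UV absorbance spectrum via Beer–Lambert.

    The absorbance at the extinction wavelength is corrected by the mean
    absorbance over the 330–350 nm scatter-baseline window before dividing
    by ε·L.  A negative baseline-corrected absorbance propagates to a
    negative concentration (flagged with a warning, never clipped).
    """
    if path_length_cm <= 0:
        raise ValueError("path length must be > 0")
    if ext.epsilon == 0:
        raise ValueError("epsilon is zero; concentration undefined")
    wavelengths = np.asarray(sorted(spectrum), dtype=float)
    if ext.wavelength not in spectrum:
        raise ValueError(f"spectrum does not cover {ext.wavelength} nm")
    lo, hi = BASELINE_WINDOW_NM
    in_window = (wavelengths >= lo) & (wavelengths <= hi)
    if not in_window.any():
        raise ValueError("spectrum does not cover the 330-350 nm baseline window")
    baseline = float(np.mean([spectrum[w] for w in wavelengths[in_window]]))
    corrected = spectrum[ext.wavelength] - baseline
    # dead-band so pure float roundoff never trips the warning
    if corrected < -1e-12 * max(1.0, abs(baseline)):
        warnings.warn(
            "baseline-corrected absorbance is negative; returning negative "
            "concentration unclipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return corrected / (ext.epsilon * path_length_cm)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file."""
    return [
        ProteinSequence(name=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.name, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def property_record(seq: ProteinSequence, remove_initiator_met: bool = False) -> dict:
    """JSON-ready summary: name, mass (kDa), predicted ε280."""
    ext = extinction_coefficient_aromatic(seq)
    return {
        "name": seq.name,
        "mass_kda": round(average_molar_mass(seq, remove_initiator_met), 4),
        "epsilon": ext.epsilon,
        "wavelength": ext.wavelength,
    }


def dumps_records(records: Iterable[dict]) -> str:
    return json.dumps(list(records), indent=2)
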