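"""Sequence-level physical attributes of helical antimicrobial peptides.

Net charge, mean hydrophobicity ``H`` and the helical hydrophobic moment
``muH`` of Eisenberg et al. are the standard desk numbers used to compare
amphipathic peptide designs.  The peptides handled here may contain two
unnatural residues beyond the 20 canonical amino acids:

* ``U`` — norvaline (Nva), an aliphatic valine surrogate;
* ``X`` — 1,2,3,4-tetrahydroisoquinoline-3-carboxylic acid (Tic), an
  aromatic, conformationally restricted tryptophan surrogate.

Hydrophobicity values for Nva and Tic are not part of any published
consensus scale, so :func:`fauchere_pliska_scale` requires them explicitly
whenever a scored sequence contains ``U`` or ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CANONICAL_CODES",
    "UNNATURAL_CODES",
    "DEFAULT_ALPHABET",
    "PeptideRecord",
    "ResidueScale",
    "PeptideProperties",
    "fauchere_pliska_scale",
    "parse_sequence",
    "net_charge",
    "mean_hydrophobicity",
    "hydrophobic_moment",
    "peptide_properties",
]

CANONICAL_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: U = norvaline (Nva), X = Tic
UNNATURAL_CODES = frozenset("UX")
DEFAULT_ALPHABET = CANONICAL_CODES | UNNATURAL_CODES

#: Fauchere & Pliska (1983) octanol/water transfer free energies, the
#: hydrophobicity scale used by the HeliQuest server.
_FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

#: Formal side-chain charges at neutral pH (His treated as neutral).
_DEFAULT_CHARGE = {code: 0 for code in DEFAULT_ALPHABET}
_DEFAULT_CHARGE.update({"R": 1, "K": 1, "D": -1, "E": -1, "H": 0})


@dataclass(frozen=True)
class PeptideRecord:
    """A named peptide as an ordered list of one-letter residue codes."""

    name: str
    residues: tuple[str, ...]

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("peptide must contain at least one residue")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(self.residues)


@dataclass(frozen=True)
class ResidueScale:
    """Per-residue hydrophobicity and formal charge maps.

    ``hydrophobicity`` may cover only part of the alphabet; scoring a
    sequence with uncovered codes is an error raised at scoring time so
    that charge-only uses (which need no hydrophobicity values) still work.
    """

    name: str
    hydrophobicity: Mapping[str, float]
    charge: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_CHARGE))

    def require_hydrophobicity(self, codes: Iterable[str]) -> None:
        missing = sorted({c for c in codes if c not in self.hydrophobicity})
        if missing:
            raise KeyError(
                f"scale '{self.name}' has no hydrophobicity entry for: "
                + ", ".join(missing)
            )

    def require_charge(self, codes: Iterable[str]) -> None:
        missing = sorted({c for c in codes if c not in self.charge})
        if missing:
            raise KeyError(
                f"scale '{self.name}' has no charge entry for: " + ", ".join(missing)
            )


@dataclass(frozen=True)
class PeptideProperties:
    """Summary attributes: net charge, H, muH and their ratio."""

    name: str
    length: int
    net_charge: int
    mean_hydrophobicity: float
    hydrophobic_moment: float

    @property
    def moment_ratio(self) -> float:
        """muH / H; undefined (raises) when H == 0."""
        if self.mean_hydrophobicity == 0:
            raise ZeroDivisionError("muH/H undefined: mean hydrophobicity is 0")
        return self.hydrophobic_moment / self.mean_hydrophobicity


def fauchere_pliska_scale(
    h_nva: float | None = None,
    h_tic: float | None = None,
    charge: Mapping[str, int] | None = None,
) -> ResidueScale:
    """The Fauchere–Pliska hydrophobicity scale, optionally extended to UAAs.

    Parameters
    ----------
    h_nva, h_tic
        Hydrophobicity values for norvaline (``U``) and Tic (``X``).  No
        published value exists for either, so there is deliberately no
        default: sequences containing ``U``/``X`` cannot be scored until
        the caller supplies them.
    charge
        Override for the formal charge map (default: R/K = +1, D/E = -1,
        everything else 0).
    """
    h = dict(_FAUCHERE_PLISKA)
    if h_nva is not None:
        h["U"] = float(h_nva)
    if h_tic is not None:
        h["X"] = float(h_tic)
    return ResidueScale(
        name="fauchere-pliska",
        hydrophobicity=h,
        charge=dict(charge) if charge is not None else dict(_DEFAULT_CHARGE),
    )


def parse_sequence(
    text: str,
    name: str = "peptide",
    alphabet: frozenset[str] | set[str] = DEFAULT_ALPHABET,
) -> PeptideRecord:
    """Parse a one-letter sequence, stripping whitespace and markup.

    Formatting characters commonly present in copied table entries
    (spaces, ``*``, ``-`` and markdown bold markers) are removed; any
    remaining character outside ``alphabet`` raises a ``ValueError``
    naming the offending character and its position.
    """
    cleaned = []
    for ch in text:
        if ch.isspace() or ch in "*-_":
            continue
        cleaned.append(ch.upper())
    if not cleaned:
        raise ValueError("empty sequence")
    for pos, ch in enumerate(cleaned, start=1):
        if ch not in alphabet:
            raise ValueError(
                f"unknown residue code {ch!r} at position {pos} of {name!r}"
            )
    return PeptideRecord(name=name, residues=tuple(cleaned))


def net_charge(p: PeptideRecord, scale: ResidueScale | None = None) -> int:
    """Sum of per-residue formal charges."""
    scale = scale or fauchere_pliska_scale()
    scale.require_charge(p.residues)
    return int(sum(scale.charge[c] for c in p.residues))


def mean_hydrophobicity(p: PeptideRecord, scale: ResidueScale) -> float:
    """Arithmetic mean of per-residue hydrophobicities over the full sequence."""
    scale.require_hydrophobicity(p.residues)
    return float(np.mean([scale.hydrophobicity[c] for c in p.residues]))


def hydrophobic_moment(
    p: PeptideRecord, scale: ResidueScale, delta_deg: float = 100.0
) -> float:
    """Helical hydrophobic moment muH (Eisenberg), full-sequence window.

    Residue ``k`` (1-based) sits at angle ``(k - 1) * delta_deg`` on the
    helical wheel; muH is the magnitude of the vector sum of the
    hydrophobicities divided by the number of residues.  The default
    100 deg/residue is the ideal alpha-helix twist.  The magnitude is
    invariant under a global rotation of the start angle, so the indexing
    origin is immaterial.
    """
    scale.require_hydrophobicity(p.residues)
    h = np.array([scale.hydrophobicity[c] for c in p.residues], dtype=float)
    ang = np.deg2rad(delta_deg) * np.arange(p.length)
    return float(np.hypot(np.dot(h, np.sin(ang)), np.dot(h, np.cos(ang))) / p.length)


def peptide_properties(
    p: PeptideRecord, scale: ResidueScale, delta_deg: float = 100.0
) -> PeptideProperties:
    """Compute all summary attributes of a peptide in one call."""
    return PeptideProperties(
        name=p.name,
        length=p.length,
        net_charge=net_charge(p, scale),
        mean_hydrophobicity=mean_hydrophobicity(p, scale),
        hydrophobic_moment=hydrophobic_moment(p, scale, delta_deg),
    )
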