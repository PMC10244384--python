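"""Core domain types shared across the pipeline.

The unit of analysis is the clonotype: the set of T cells carrying an
identical TCR, matched here by the amino-acid sequence of the CDR3 region of
the beta chain (CDR3b), the principal determinant of antigen specificity.
Structural avidity is the strength of monomeric pMHC-TCR binding, quantified
as the dissociation half-life T1/2 in seconds; T1/2 > 60 s defines the
high-avidity class and T1/2 > 10 s the intermediate/high band used in the
clustering hotspot analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The 20 canonical amino acids, upper case, no ambiguity codes or gaps.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

#: Half-life (s) above which a TCR is labelled high avidity. Exactly 60 s is
#: labelled low: the class definitions are strict inequalities (> 60 s high,
#: < 60 s low), leaving the boundary unassigned, and we resolve it downward.
HIGH_AVIDITY_THRESHOLD_S = 60.0

#: Half-life (s) above which a TCR counts as intermediate-or-high avidity in
#: the clustering hotspot analysis.
INTERMEDIATE_AVIDITY_THRESHOLD_S = 10.0


def validate_cdr3(sequence: str) -> str:
    """Upper-case and validate a CDR3b amino-acid string.

    Raises ValueError naming the first offending position if a character is
    not one of the 20 canonical amino-acid letters.
    """
    seq = sequence.strip().upper()
    for i, ch in enumerate(seq):
        if ch not in AA_SET:
            raise ValueError(
                f"invalid amino-acid character {ch!r} at position {i + 1} "
                f"in CDR3 sequence {sequence!r}"
            )
    return seq


@dataclass
class TcrClonotype:
    """One TCR clonotype keyed by its CDR3b amino-acid sequence."""

    tcr_id: str
    cdr3b: str
    pmhc: Optional[str] = None
    compartment: Optional[str] = None
    count: Optional[int] = None
    halflife_s: Optional[float] = None
    v_gene: Optional[str] = None
    j_gene: Optional[str] = None

    def __post_init__(self) -> None:
        self.cdr3b = validate_cdr3(self.cdr3b)

    @property
    def is_high_avidity(self) -> Optional[bool]:
        """True iff the measured half-life exceeds 60 s; None if unmeasured."""
        if self.halflife_s is None:
            return None
        return self.halflife_s > HIGH_AVIDITY_THRESHOLD_S


@dataclass
class ExposureProfile:
    """Per-residue relative solvent exposure of one TCR's modeled CDR3b.

    ``exposed_fraction[i]`` is the relative solvent-excluded surface area of
    CDR3b position ``i`` (surface area in the modeled TCR normalised by the
    residue's surface area in a reference state), a fraction in [0, 1].
    Structure modeling happens upstream; this object only carries its output.
    """

    tcr_id: str
    exposed_fraction: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.exposed_fraction, dtype=float)
        if arr.ndim != 1:
            raise ValueError("exposed_fraction must be one-dimensional")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(
                f"exposure fractions for {self.tcr_id!r} must be finite and in [0, 1]"
            )
        self.exposed_fraction = arr

    def __len__(self) -> int:
        return self.exposed_fraction.shape[0]


@dataclass
class ContactCounts:
    """Modeled atomic contacts for one TCR-pMHC complex.

    Contact detection (distance cutoffs, atom typing) is upstream of this
    package; counts are taken at face value. ``halflife_s`` is optional for
    prediction-only rows.
    """

    complex_id: str
    n_apolar: int
    n_polar: int
    halflife_s: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("n_apolar", "n_polar"):
            value = getattr(self, name)
            if value != int(value) or value < 0:
                raise ValueError(
                    f"{name} must be a nonnegative integer, got {value!r} "
                    f"for complex {self.complex_id!r}"
                )
            setattr(self, name, int(value))
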