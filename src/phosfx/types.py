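"""Core domain records shared by every stage of the pipeline.

Positions are 1-based in records and files (the convention of site tables
and of the field at large); array indices are 0-based and conversion
happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Residues that can be phosphorylated.
STY = frozenset("STY")

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Pad symbol used by the fixed-length site window.
PAD_SYMBOL = "*"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession.

    ``sequence`` is uppercase over the 20 standard letters plus 'X' for
    anything non-standard.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise ValueError(
                f"position {position} out of bounds for protein "
                f"{self.id!r} of length {len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SiteRecord:
    """A candidate phosphosite: an S/T/Y residue with a functional label.

    ``label`` is 1 if phosphorylation at this site has a validated
    functional effect, 0 otherwise.
    """

    protein_id: str
    position: int  # 1-based
    residue: str
    label: int

    def __post_init__(self) -> None:
        if self.residue not in STY:
            raise ValueError(
                f"site {self.protein_id}:{self.position}: residue "
                f"{self.residue!r} is not S, T or Y"
            )
        if self.label not in (0, 1):
            raise ValueError(
                f"site {self.protein_id}:{self.position}: label must be 0 or 1"
            )
        if self.position < 1:
            raise ValueError(
                f"site {self.protein_id}:{self.position}: positions are 1-based"
            )

    def validate_against(self, protein: ProteinRecord) -> None:
        """Check the record is consistent with its protein sequence."""
        if protein.id != self.protein_id:
            raise ValueError(
                f"site references protein {self.protein_id!r}, got {protein.id!r}"
            )
        actual = protein.residue(self.position)
        if actual != self.residue:
            raise ValueError(
                f"site {self.protein_id}:{self.position}: residue mismatch "
                f"(table says {self.residue!r}, sequence has {actual!r})"
            )


@dataclass(frozen=True)
class PPIEffectRecord:
    """Effect of phosphorylating one site on protein A on the A-B interaction.

    ``label`` is 1 for enhancement of the interaction, 0 for inhibition.
    The site lives on protein A; the key (A, B, position) is directional.
    """

    protein_a_id: str
    protein_b_id: str
    position: int  # 1-based, on protein A
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("effect label must be 0 (inhibition) or 1 (enhancement)")
        if self.position < 1:
            raise ValueError("positions are 1-based")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.protein_a_id, self.protein_b_id, self.position)

    def validate_against(self, protein_a: ProteinRecord) -> None:
        res = protein_a.residue(self.position)
        if res not in STY:
            raise ValueError(
                f"effect record {self.key}: position {self.position} of "
                f"{self.protein_a_id!r} is {res!r}, not S/T/Y"
            )


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-residue embedding of one protein: an L x D real matrix."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("embedding must be a non-empty L x D matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"embedding for {self.protein_id!r} has non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Prediction:
    """A binary prediction: probability pair (p_class0, p_class1) + hard label.

    The hard label is 1 when p_class1 exceeds 0.5; an exact tie goes to
    class 0 (the conservative call for both tasks).
    """

    probs: tuple[float, float]
    label: int = field(init=False)

    def __post_init__(self) -> None:
        p0, p1 = float(self.probs[0]), float(self.probs[1])
        if not (np.isfinite(p0) and np.isfinite(p1)):
            raise ValueError("probabilities must be finite")
        if abs(p0 + p1 - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1, got {p0 + p1}")
        object.__setattr__(self, "probs", (p0, p1))
        object.__setattr__(self, "label", int(p1 > 0.5))

    @property
    def p_positive(self) -> float:
        return self.probs[1]
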