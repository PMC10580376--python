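"""Immune receptor domain type.

A receptor is identified by the triple (junction_aa, v_call, j_call): the
amino-acid junction (CDR3 plus conserved flanks) together with the V and J
gene masks. Two receptors are "the same sequence" iff all three fields match;
the generation probability is an annotation, not part of the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: The 20 standard amino acids, one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


def is_valid_junction(junction_aa: str) -> bool:
    """True iff *junction_aa* is non-empty and uses only standard residues."""
    return bool(junction_aa) and set(junction_aa) <= _AA_SET


@dataclass(frozen=True, slots=True)
class Receptor:
    """One immune receptor chain.

    Parameters
    ----------
    junction_aa
        Amino-acid junction over the 20-letter alphabet; non-empty.
    v_call, j_call
        V- and J-gene identifiers.
    pgen
        Generation probability in [0, 1] under the active recombination
        model, or ``None`` if not (yet) computed. Excluded from equality
        and hashing.
    """

    junction_aa: str
    v_call: str
    j_call: str
    pgen: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if not is_valid_junction(self.junction_aa):
            raise ValidationError(
                f"invalid amino-acid junction: {self.junction_aa!r}"
            )
        if self.pgen is not None and not (0.0 <= self.pgen <= 1.0):
            raise ValidationError(f"pgen outside [0, 1]: {self.pgen!r}")

    @property
    def identity(self) -> tuple[str, str, str]:
        """The (junction_aa, v_call, j_call) identity triple."""
        return (self.junction_aa, self.v_call, self.j_call)

    def with_pgen(self, pgen: float) -> "Receptor":
        """Return a copy annotated with *pgen*."""
        return Receptor(self.junction_aa, self.v_call, self.j_call, pgen)
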