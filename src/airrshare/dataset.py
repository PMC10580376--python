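"""Repertoire dataset container shared by the simulator and the bias audit."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ValidationError
from .receptors import Receptor

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class Repertoire:
    """One individual's repertoire: a set of unique receptors plus a label."""

    repertoire_id: str
    label: str | None  # POSITIVE / NEGATIVE / None (unlabeled baseline)
    receptors: set[Receptor]


@dataclass
class RepertoireDataset:
    """A cohort of repertoires with labels and a ground-truth signal manifest.

    The manifest records every (signal receptor, repertoire_id) placement the
    simulator made — the dataset's receptor-level ground truth.
    """

    repertoires: list[Repertoire]
    manifest: list[tuple[Receptor, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.repertoire_id for r in self.repertoires]
        if len(set(ids)) != len(ids):
            raise ValidationError("repertoire_ids are not unique")
        labels = {r.label for r in self.repertoires} - {None}
        if not labels <= {POSITIVE, NEGATIVE}:
            raise ValidationError(f"labels must be binary, got {sorted(labels)}")
        by_id = {r.repertoire_id: r for r in self.repertoires}
        for rec, rep_id in self.manifest:
            rep = by_id.get(rep_id)
            if rep is None:
                raise ValidationError(f"manifest references unknown repertoire {rep_id}")
            if rep.label != POSITIVE:
                raise ValidationError(
                    f"manifest placement in non-positive repertoire {rep_id}"
                )

    @property
    def n_repertoires(self) -> int:
        return len(self.repertoires)

    def by_label(self, label: str) -> list[Repertoire]:
        return [r for r in self.repertoires if r.label == label]

    def occurrence_counts(self) -> Counter:
        """Receptor -> number of repertoires carrying it (all labels)."""
        counts: Counter = Counter()
        for rep in self.repertoires:
            counts.update(rep.receptors)
        return counts

    def label_counts(self, receptor: Receptor) -> tuple[int, int]:
        """(positive, negative) carrying-repertoire counts for one receptor."""
        c_p = sum(1 for r in self.repertoires if r.label == POSITIVE and receptor in r.receptors)
        c_n = sum(1 for r in self.repertoires if r.label == NEGATIVE and receptor in r.receptors)
        return c_p, c_n

    def mean_unique_per_repertoire(self) -> float:
        return sum(len(r.receptors) for r in self.repertoires) / len(self.repertoires)

    def signal_identities(self) -> set[tuple[str, str, str]]:
        return {rec.identity for rec, _ in self.manifest}
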