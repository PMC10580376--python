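"""Empirical models of population incidence conditional on generation probability.

A cohort's public sequences (those seen in more than one individual) show a
characteristic relation between how easily a sequence is generated by V(D)J
recombination (its pgen) and how widely it is shared. This module learns that
relation as a binned conditional distribution — rows are pgen bins, columns
are population-incidence-fraction bins — separately for immune-state signal
sequences and for the remaining public background, and samples sharing levels
from it during simulation.

All bins are half-open, left-closed [left, right); the top incidence bin is
closed at 1. Values outside the binned range clamp to the first/last bin.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .errors import ConfigurationError, ModelUnusableError, ValidationError
from .receptors import Receptor

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-9

#: Default log10-pgen breakpoints: four bins (<1e-12), [1e-12,1e-9),
#: [1e-9,1e-6), [>=1e-6], grouping three log-decades each. Configurable.
DEFAULT_PGEN_LOG10_EDGES = (-12.0, -9.0, -6.0)

#: Default population-incidence-fraction bin edges. The first bin starts at 0
#: (a public sequence's smallest possible fraction, 2/N, always lands there).
DEFAULT_INCIDENCE_EDGES = (0.0, 0.02, 0.05, 0.1, 0.2, 0.3, 1.0)


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (publicness arithmetic)."""
    return int(math.floor(x + 0.5))


def _snap_ceil(x: float) -> int:
    """Ceiling with a tolerance snap for edges like 0.02 x 500 = 10.000..02."""
    r = round(x)
    return int(r) if abs(x - r) < 1e-9 else int(math.ceil(x))


def count_bounds(left: float, right: float, denominator: int) -> tuple[int, int]:
    """Smallest/largest repertoire counts whose incidence fraction falls in
    [left, right) (right-inclusive when the bin is closed at 1).

    Returns (lo, hi); lo > hi means no count can represent the bin at this
    cohort size.
    """
    lo = _snap_ceil(left * denominator)
    hi = denominator if right >= 1.0 else _snap_ceil(right * denominator) - 1
    return lo, hi


@dataclass(frozen=True)
class PgenBinning:
    """Half-open log10-pgen bins defined by strictly increasing breakpoints.

    ``k`` breakpoints define ``k + 1`` bins; pgen below the first breakpoint
    maps to the first bin and at/above the last to the last (clamping), so
    every pgen in (0, 1] maps to exactly one bin. pgen = 0 maps to the first.
    """

    edges: tuple[float, ...] = DEFAULT_PGEN_LOG10_EDGES

    def __post_init__(self):
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))
        if len(self.edges) < 1 or np.any(np.diff(self.edges) <= 0):
            raise ConfigurationError("pgen edges must be strictly increasing, >= 1")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def bin_of(self, pgen: float) -> int:
        if not (0.0 <= pgen <= 1.0):
            raise ValidationError(f"pgen outside [0, 1]: {pgen}")
        if pgen == 0.0:
            return 0
        return int(np.searchsorted(self.edges, math.log10(pgen), side="right"))


@dataclass(frozen=True)
class IncidenceBinning:
    """Half-open incidence-fraction bins from a full ascending edge list in [0, 1]."""

    edges: tuple[float, ...] = DEFAULT_INCIDENCE_EDGES

    def __post_init__(self):
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))
        if len(self.edges) < 2 or np.any(np.diff(self.edges) <= 0):
            raise ConfigurationError("incidence edges must be strictly increasing")
        if self.edges[0] < 0 or self.edges[-1] > 1:
            raise ConfigurationError("incidence edges must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_of(self, fraction: float) -> int:
        if not (0.0 <= fraction <= 1.0):
            raise ValidationError(f"incidence fraction outside [0, 1]: {fraction}")
        idx = int(np.searchsorted(self.edges, fraction, side="right")) - 1
        return min(max(idx, 0), self.n_bins - 1)

    def interval(self, idx: int) -> tuple[float, float]:
        return self.edges[idx], self.edges[idx + 1]


@dataclass
class IncidenceModel:
    """Row-normalised table of incidence-bin probabilities per pgen bin.

    Rows with no training data are "empty" (``row_counts`` zero, table row
    all zero) and are never sampled directly; queries against an empty row
    borrow the nearest non-empty lower-pgen row (conservative: lower pgen
    bins carry lower sharing) with a logged warning.
    """

    pgen_binning: PgenBinning
    incidence_binning: IncidenceBinning
    table: np.ndarray
    component_label: str
    row_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (self.pgen_binning.n_bins, self.incidence_binning.n_bins):
            raise ConfigurationError(
                f"table shape {self.table.shape} does not match binning "
                f"({self.pgen_binning.n_bins} x {self.incidence_binning.n_bins})"
            )
        if self.component_label not in ("signal", "public"):
            raise ConfigurationError(
                f"component_label must be 'signal' or 'public', got {self.component_label!r}"
            )
        if self.row_counts is None:
            # infer: any row with mass counts as populated
            self.row_counts = (self.table.sum(axis=1) > 0).astype(int)
        self.row_counts = np.asarray(self.row_counts, dtype=int)
        if (self.table < 0).any() or (self.table > 1).any():
            raise ValidationError("table entries outside [0, 1]")
        for i, row in enumerate(self.table):
            if self.row_counts[i] > 0 and abs(row.sum() - 1.0) > _ROW_SUM_TOL:
                raise ValidationError(f"row {i} sums to {row.sum():.12f}, not 1")
            if self.row_counts[i] == 0 and row.sum() != 0:
                raise ValidationError(f"row {i} marked empty but carries mass")

    def row_is_empty(self, idx: int) -> bool:
        return self.row_counts[idx] == 0

    def __eq__(self, other) -> bool:
        if not isinstance(other, IncidenceModel):
            return NotImplemented
        return (
            self.pgen_binning == other.pgen_binning
            and self.incidence_binning == other.incidence_binning
            and self.component_label == other.component_label
            and np.array_equal(self.table, other.table)
            and np.array_equal(self.row_counts > 0, other.row_counts > 0)
        )

    def _effective_row(self, pgen: float) -> int:
        """Row index to use for *pgen*, borrowing downward across empty rows."""
        return self._effective_row_index(self.pgen_binning.bin_of(pgen))

    def _effective_row_index(self, idx: int) -> int:
        if not self.row_is_empty(idx):
            return idx
        for j in range(idx - 1, -1, -1):
            if not self.row_is_empty(j):
                logger.warning(
                    "%s incidence model: pgen bin %d is empty; borrowing lower bin %d",
                    self.component_label, idx, j,
                )
                return j
        for j in range(idx + 1, self.pgen_binning.n_bins):
            if not self.row_is_empty(j):
                logger.warning(
                    "%s incidence model: pgen bin %d empty with no lower data; "
                    "borrowing higher bin %d", self.component_label, idx, j,
                )
                return j
        raise ModelUnusableError(
            f"{self.component_label} incidence model has no populated rows"
        )


def calibrate(
    occurrences: Mapping[Receptor, int],
    total_repertoires: int,
    pgen_of: Mapping | Callable[[Receptor], float] | None,
    pgen_binning: PgenBinning | None = None,
    incidence_binning: IncidenceBinning | None = None,
    signal_ids: Iterable = (),
    signal_denominator: int | None = None,
) -> tuple[IncidenceModel, IncidenceModel]:
    """Learn (signal, public) incidence models from observed sharing counts.

    Parameters
    ----------
    occurrences
        Mapping receptor -> number of repertoires carrying it; public only
        (every count must be >= 2).
    total_repertoires
        Cohort size; denominator for the public component's incidence fraction.
    pgen_of
        Mapping or callable supplying each receptor's pgen; ``None`` uses the
        receptors' own ``pgen`` annotation.
    signal_ids
        Identities (receptors or (junction, v, j) triples) of the perceived
        true signal sequences; these train the signal component, everything
        else the public component.
    signal_denominator
        Denominator for the signal component's incidence fraction — by
        convention the positive-class repertoire count. ``None`` falls back
        to *total_repertoires*.

    Each unique sequence contributes once to exactly one cell of exactly one
    component; rows are normalised to probability distributions.
    """
    if total_repertoires < 1:
        raise ValidationError("total_repertoires must be positive")
    pgen_binning = pgen_binning or PgenBinning()
    incidence_binning = incidence_binning or IncidenceBinning()
    sig_den = signal_denominator if signal_denominator is not None else total_repertoires

    sig_set = {r.identity if isinstance(r, Receptor) else tuple(r) for r in signal_ids}

    def lookup_pgen(rec: Receptor) -> float | None:
        if pgen_of is None:
            return rec.pgen
        if callable(pgen_of):
            return pgen_of(rec)
        return pgen_of.get(rec, pgen_of.get(rec.identity))  # type: ignore[union-attr]

    missing = [rec.identity for rec in occurrences if lookup_pgen(rec) is None]
    if missing:
        raise ValidationError(
            f"{len(missing)} sequences lack a generation probability; "
            f"first offenders: {missing[:5]}"
        )

    shape = (pgen_binning.n_bins, incidence_binning.n_bins)
    tallies = {"signal": np.zeros(shape), "public": np.zeros(shape)}
    for rec, count in occurrences.items():
        if count < 2:
            raise ValidationError(
                f"sequence {rec.identity} observed in {count} repertoire(s); "
                "public sequences require counts >= 2"
            )
        comp = "signal" if rec.identity in sig_set else "public"
        den = sig_den if comp == "signal" else total_repertoires
        if count > den:
            raise ValidationError(
                f"sequence {rec.identity}: count {count} exceeds denominator {den}"
            )
        pbin = pgen_binning.bin_of(lookup_pgen(rec))
        ibin = incidence_binning.bin_of(count / den)
        tallies[comp][pbin, ibin] += 1

    out = []
    for label in ("signal", "public"):
        t = tallies[label]
        row_counts = t.sum(axis=1).astype(int)
        table = np.zeros_like(t)
        nz = row_counts > 0
        table[nz] = t[nz] / t[nz].sum(axis=1, keepdims=True)
        out.append(
            IncidenceModel(pgen_binning, incidence_binning, table, label, row_counts)
        )
    return out[0], out[1]


def sample_incidence_count(
    model: IncidenceModel,
    pgen: float,
    denominator_repertoires: int,
    rng: np.random.Generator,
) -> int:
    """Draw a carrying-repertoire count for a public sequence of given pgen.

    Draws an incidence bin from the pgen row's categorical distribution, a
    fraction uniformly within the bin (maximum-entropy choice — only the
    bin-level distribution is modelled), converts to a count by rounding
    half up, clips the count so its incidence fraction stays inside the
    drawn half-open bin (when the cohort is large enough to represent it),
    and clamps to [2, denominator]: a public sequence is by definition
    shared.
    """
    if denominator_repertoires < 1:
        raise ValidationError("denominator_repertoires must be positive")
    den = denominator_repertoires
    row = model.table[model._effective_row(pgen)]
    ibin = int(rng.choice(model.incidence_binning.n_bins, p=row))
    left, right = model.incidence_binning.interval(ibin)
    frac = float(rng.uniform(left, right))
    count = round_half_up(frac * den)
    lo, hi = count_bounds(left, right, den)
    if lo <= hi:
        count = min(max(count, lo), hi)
    return int(min(max(count, 2), den))


def max_incidence_fraction(model: IncidenceModel, pgen: float) -> float:
    """Right edge of the highest incidence bin with mass in pgen's row.

    The per-sequence sharing cap used by witness-rate feasibility: a
    sequence of this pgen cannot be seen in more than this fraction of the
    cohort under the model. Deterministic.
    """
    row = model.table[model._effective_row(pgen)]
    nz = np.flatnonzero(row > 0)
    if nz.size == 0:  # pragma: no cover - empty rows are never effective
        raise ModelUnusableError("effective row carries no mass")
    return float(model.incidence_binning.edges[nz[-1] + 1])


# -- persistence -----------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: IncidenceModel, path) -> None:
    """Write a model to JSON (or TSV when *path* ends in .tsv). Human-readable."""
    path = str(path)
    rows = [
        (None if model.row_is_empty(i) else [float(x) for x in model.table[i]])
        for i in range(model.pgen_binning.n_bins)
    ]
    if path.endswith(".tsv"):
        with open(path, "w") as fh:
            fh.write(f"#version\t{_FORMAT_VERSION}\n")
            fh.write(f"#component_label\t{model.component_label}\n")
            fh.write("#pgen_log10_edges\t" + ",".join(map(str, model.pgen_binning.edges)) + "\n")
            fh.write("#incidence_edges\t" + ",".join(map(str, model.incidence_binning.edges)) + "\n")
            header = ["pgen_bin"] + [
                f"[{l},{r})" for l, r in
                zip(model.incidence_binning.edges[:-1], model.incidence_binning.edges[1:])
            ]
            fh.write("\t".join(header) + "\n")
            for i, row in enumerate(rows):
                cells = ["NA"] * model.incidence_binning.n_bins if row is None else [
                    repr(x) for x in row
                ]
                fh.write("\t".join([str(i)] + cells) + "\n")
        return
    doc = {
        "version": _FORMAT_VERSION,
        "component_label": model.component_label,
        "pgen_log10_edges": list(model.pgen_binning.edges),
        "incidence_edges": list(model.incidence_binning.edges),
        "rows": rows,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def _model_from_parts(version, label, pgen_edges, inc_edges, rows) -> IncidenceModel:
    if version != _FORMAT_VERSION:
        raise ValidationError(f"unknown incidence model format version: {version!r}")
    pgen_binning = PgenBinning(tuple(pgen_edges))
    incidence_binning = IncidenceBinning(tuple(inc_edges))
    table = np.zeros((pgen_binning.n_bins, incidence_binning.n_bins))
    row_counts = np.zeros(pgen_binning.n_bins, dtype=int)
    if len(rows) != pgen_binning.n_bins:
        raise ValidationError(
            f"expected {pgen_binning.n_bins} rows, found {len(rows)}"
        )
    for i, row in enumerate(rows):
        if row is None:
            continue
        row = np.asarray(row, dtype=float)
        if abs(row.sum() - 1.0) > _ROW_SUM_TOL:
            raise ValidationError(f"row {i} sums to {row.sum():.12f}, not 1")
        table[i] = row
        row_counts[i] = 1
    return IncidenceModel(pgen_binning, incidence_binning, table, label, row_counts)


def load_model(path) -> IncidenceModel:
    """Load a model saved by :func:`save_model` (JSON or TSV); validates rows."""
    path = str(path)
    try:
        if path.endswith(".tsv"):
            meta, rows = {}, []
            with open(path) as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if line.startswith("#"):
                        key, _, val = line[1:].partition("\t")
                        meta[key] = val
                    elif line.startswith("pgen_bin") or not line:
                        continue
                    else:
                        cells = line.split("\t")[1:]
                        rows.append(
                            None if cells[0] == "NA" else [float(c) for c in cells]
                        )
            return _model_from_parts(
                int(meta["version"]),
                meta["component_label"],
                [float(x) for x in meta["pgen_log10_edges"].split(",")],
                [float(x) for x in meta["incidence_edges"].split(",")],
                rows,
            )
        with open(path) as fh:
            doc = json.load(fh)
        return _model_from_parts(
            doc.get("version"),
            doc.get("component_label"),
            doc["pgen_log10_edges"],
            doc["incidence_edges"],
            doc["rows"],
        )
    except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
        raise ValidationError(f"malformed incidence model file {path}: {exc}") from exc
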