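"""Four-stage cohort simulation with realistic receptor sharing.

Stages: (i) witness-rate feasibility assessment, (ii) baseline repertoire
generation from a V(D)J engine, (iii) public-component correction — a
user-chosen share of the cohort's unique sequences is made public, with each
public sequence's carrying-repertoire count drawn from an empirical
incidence-vs-pgen model — and (iv) signal implantation into positive-class
repertoires, again respecting the incidence model. A naive implantation mode
(uniform placement, no public correction) is provided as the contrast that
exhibits generation-probability discordance bias.

Baseline generation follows the naive-sampling recipe: draw from the
recombination model and retain only unique sequences per repertoire. The
public-component correction generates its own fresh sequence pool (it does
not consume a stage-ii artifact) and preserves per-repertoire depth: public
copies occupy slots that private sequences would otherwise fill.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np

from .dataset import NEGATIVE, POSITIVE, Repertoire, RepertoireDataset
from .engines import Engine, ToyEngine, get_engine
from .errors import FeasibilityError, ValidationError
from .incidence import (
    IncidenceModel,
    max_incidence_fraction,
    round_half_up,
    sample_incidence_count,
)
from .receptors import Receptor
from .rng import substream

logger = logging.getLogger(__name__)

#: Relative tolerance on reaching the implantation instance budget.
WITNESS_TOTAL_TOLERANCE = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    witness_rate is the mean number of signal sequences per positive
    repertoire (the canonical internal unit); the per-10^5-receptors form is
    derived for display as ``witness_rate_per_1e5``.
    """

    n_repertoires: int
    depth: int
    positive_fraction: float = 0.5
    depth_spread: int = 0
    public_fraction: float = 0.10
    witness_rate: float = 0.0
    n_signal_pool_used: int | None = None
    engine: str = "toy"
    seed: int = 0

    def __post_init__(self):
        if self.n_repertoires < 1:
            raise ValidationError("n_repertoires must be >= 1")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValidationError("positive_fraction must be in (0, 1)")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.depth_spread < 0 or self.depth_spread >= self.depth:
            if self.depth_spread != 0:
                raise ValidationError("depth_spread must be in [0, depth)")
        if not (0.0 <= self.public_fraction <= 1.0):
            raise ValidationError("public_fraction must be in [0, 1]")
        if self.witness_rate < 0:
            raise ValidationError("witness_rate must be >= 0")

    @property
    def n_positive(self) -> int:
        return round_half_up(self.positive_fraction * self.n_repertoires)

    @property
    def witness_rate_per_1e5(self) -> float:
        return self.witness_rate / self.depth * 1e5

    def semantic_dict(self) -> dict:
        return {
            "n_repertoires": self.n_repertoires,
            "depth": self.depth,
            "positive_fraction": self.positive_fraction,
            "depth_spread": self.depth_spread,
            "public_fraction": self.public_fraction,
            "witness_rate": self.witness_rate,
            "n_signal_pool_used": self.n_signal_pool_used,
            "engine": self.engine if isinstance(self.engine, str) else repr(self.engine),
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class FeasibilityReport:
    """Required vs. achievable signal totals for a desired witness rate."""

    required_total: int
    achievable_total: int
    per_sequence_caps: list[tuple[tuple[str, str, str], float, int]]
    feasible: bool
    guidance: str
    witness_rate: float
    witness_rate_per_1e5: float

    def to_dict(self) -> dict:
        return {
            "required_total": self.required_total,
            "achievable_total": self.achievable_total,
            "feasible": self.feasible,
            "witness_rate": self.witness_rate,
            "witness_rate_per_1e5": self.witness_rate_per_1e5,
            "guidance": self.guidance,
            "per_sequence_caps": [
                {"junction_aa": i[0], "v_call": i[1], "j_call": i[2],
                 "pgen": p, "cap": c}
                for i, p, c in self.per_sequence_caps
            ],
        }


def _pool_used(signal_pool: list[Receptor], config: SimConfig) -> list[Receptor]:
    if config.n_signal_pool_used is None:
        return list(signal_pool)
    return list(signal_pool)[: config.n_signal_pool_used]


def assess_feasibility(
    signal_pool: list[Receptor],
    config: SimConfig,
    signal_model: IncidenceModel,
) -> FeasibilityReport:
    """Stage i: can the desired witness rate be met with this signal pool?

    required_total = round(n_positive x witness_rate) signal instances must
    be placed; each pool sequence can carry at most
    floor(max_incidence_fraction(pgen) x n_repertoires) instances under the
    incidence model. Deterministic given its inputs.
    """
    pool = _pool_used(signal_pool, config)
    if not pool:
        raise ValidationError("signal pool is empty")
    missing = [r.identity for r in pool if r.pgen is None]
    if missing:
        raise ValidationError(
            f"{len(missing)} signal sequences lack pgen; first: {missing[:5]}"
        )
    required = round_half_up(config.n_positive * config.witness_rate)
    caps = []
    zero_pgen = 0
    for rec in pool:
        if rec.pgen == 0.0:
            caps.append((rec.identity, 0.0, 0))
            zero_pgen += 1
        else:
            frac = max_incidence_fraction(signal_model, rec.pgen)
            caps.append((rec.identity, rec.pgen, int(math.floor(frac * config.n_repertoires))))
    achievable = sum(c for _, _, c in caps)
    feasible = achievable >= required
    lines = [
        f"required signal instances: {required} "
        f"({config.n_positive} positive repertoires x witness rate {config.witness_rate})",
        f"achievable signal instances: {achievable} "
        f"(sum of per-sequence incidence caps over {len(pool)} pool sequences)",
    ]
    if zero_pgen:
        lines.append(
            f"warning: {zero_pgen} pool sequences have pgen = 0 under the active "
            "engine and can never be made public"
        )
    if not feasible:
        shortfall = required - achievable
        need = math.ceil(required / max(achievable / len(pool), 1e-12)) if achievable else None
        lines.append(
            f"INFEASIBLE: short by {shortfall} instances. Supply a larger signal "
            f"pool{f' (roughly {need} sequences at similar pgen)' if need else ''} "
            "or lower the witness rate."
        )
    else:
        lines.append("feasible: the witness rate can be met.")
    return FeasibilityReport(
        required, achievable, caps, feasible, "\n".join(lines),
        config.witness_rate, config.witness_rate_per_1e5,
    )


# -- stage ii: baseline ----------------------------------------------------

def _rep_depths(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.depth_spread == 0:
        return np.full(config.n_repertoires, config.depth, dtype=int)
    return rng.integers(
        config.depth - config.depth_spread,
        config.depth + config.depth_spread + 1,
        size=config.n_repertoires,
    )


def _sample_unique(engine: Engine, target: int, rng: np.random.Generator) -> set[Receptor]:
    """Draw until *target* unique receptors are retained (duplicates dropped)."""
    seen: dict[tuple, Receptor] = {}
    while len(seen) < target:
        short = target - len(seen)
        batch = max(int(short * 1.05) + 8, 16)
        if isinstance(engine, ToyEngine):
            junctions, v_calls, j_calls, pgen = engine.sample_arrays(batch, rng)
            for k in range(batch):
                key = (junctions[k], v_calls[k], j_calls[k])
                if key not in seen:
                    seen[key] = Receptor(key[0], str(key[1]), str(key[2]), float(pgen[k]))
                    if len(seen) == target:
                        break
        else:
            for rec in engine.sample(batch, rng):
                if rec.identity not in seen:
                    seen[rec.identity] = rec
                    if len(seen) == target:
                        break
    return set(seen.values())


def _sample_unique_list(
    engine: Engine,
    batch: int,
    rng: np.random.Generator,
    seen: set[tuple],
) -> list[Receptor]:
    """Draw a batch and keep receptors not yet in *seen* (which is updated).

    Returns at most *batch* fresh receptors in generation order; the caller
    loops if it needs an exact count.
    """
    out: list[Receptor] = []
    if isinstance(engine, ToyEngine):
        junctions, v_calls, j_calls, pgens = engine.sample_arrays(batch, rng)
        for k in range(batch):
            key = (junctions[k], str(v_calls[k]), str(j_calls[k]))
            if key not in seen:
                seen.add(key)
                out.append(Receptor(key[0], key[1], key[2], float(pgens[k])))
    else:
        for rec in engine.sample(batch, rng):
            if rec.identity not in seen:
                seen.add(rec.identity)
                out.append(rec)
    return out


def generate_baseline(
    config: SimConfig,
    engine: Engine | str | None = None,
    rng: np.random.Generator | None = None,
) -> RepertoireDataset:
    """Stage ii: naive baseline — each repertoire sampled i.i.d. from the engine.

    Within a repertoire only unique sequences are retained; sharing between
    repertoires arises solely from convergent recombination. Unlabeled.
    """
    engine = get_engine(engine if engine is not None else config.engine)
    rng = rng if rng is not None else substream(config.seed, "baseline")
    depths = _rep_depths(config, rng)
    reps = [
        Repertoire(f"rep_{i:05d}", None, _sample_unique(engine, int(depths[i]), rng))
        for i in range(config.n_repertoires)
    ]
    return RepertoireDataset(
        reps, provenance={"stage": "baseline", "config": config.semantic_dict(),
                          "config_hash": config.config_hash()},
    )


# -- stage iii: public-component correction --------------------------------

def _counts_for_pgens(
    model: IncidenceModel,
    pgens: np.ndarray,
    denominator: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised incidence-count draws, grouped by pgen bin.

    Matches :func:`~airrshare.incidence.sample_incidence_count` in
    distribution: round half up, clip into the drawn half-open bin where
    the cohort size can represent it, clamp to [2, denominator].
    """
    from .incidence import count_bounds

    binning = model.pgen_binning
    inc = model.incidence_binning
    edges_l = np.array(inc.edges[:-1])
    edges_r = np.array(inc.edges[1:])
    bounds = [count_bounds(l, r, denominator) for l, r in zip(edges_l, edges_r)]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    with np.errstate(divide="ignore"):
        logs = np.where(pgens > 0, np.log10(np.maximum(pgens, 1e-320)), -np.inf)
    bins = np.searchsorted(binning.edges, logs, side="right")
    bins[pgens == 0] = 0
    counts = np.empty(len(pgens), dtype=int)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        row = model.table[model._effective_row_index(int(b))]
        ibins = rng.choice(inc.n_bins, size=idx.size, p=row)
        fracs = rng.uniform(edges_l[ibins], edges_r[ibins])
        c = np.floor(fracs * denominator + 0.5).astype(int)
        representable = lo[ibins] <= hi[ibins]
        c = np.where(representable, np.clip(c, lo[ibins], hi[ibins]), c)
        counts[idx] = np.clip(c, 2, denominator)
    return counts


def correct_public_component(
    config: SimConfig,
    engine: Engine | str | None = None,
    public_model: IncidenceModel | None = None,
    rng: np.random.Generator | None = None,
) -> RepertoireDataset:
    """Stage iii: build a cohort whose sharing obeys the incidence model.

    A fresh pool of unique sequences is generated; a ``public_fraction``
    share of them is made public, each with a carrying-repertoire count
    drawn from the model (denominator: the full cohort size) and placed in
    that many distinct repertoires; the rest stay private. Per-repertoire
    depth is preserved: public copies fill slots private sequences would
    have taken. Unlabeled.
    """
    if public_model is None:
        from .fixtures import default_public_model

        public_model = default_public_model()
    engine = get_engine(engine if engine is not None else config.engine)
    rng = rng if rng is not None else substream(config.seed, "public_correction")
    n = config.n_repertoires
    depths = _rep_depths(config, rng)
    total_slots = int(depths.sum())
    f = config.public_fraction

    # Phase A: decide unique sequences (public w.p. public_fraction, with
    # model-drawn counts) until the slot budget is covered.
    publics: list[Receptor] = []
    public_counts: list[int] = []
    privates: list[Receptor] = []
    seen: set[tuple] = set()
    slots_used = 0
    while slots_used < total_slots:
        short = total_slots - slots_used
        batch = max(min(int(short * 1.1) + 16, 500_000), 64)
        fresh = _sample_unique_list(engine, batch, rng, seen)
        flags = rng.random(len(fresh)) < f
        pub_batch = [rec for rec, flag in zip(fresh, flags) if flag]
        counts_batch = (
            _counts_for_pgens(
                public_model, np.array([r.pgen for r in pub_batch]), n, rng
            )
            if pub_batch else np.empty(0, dtype=int)
        )
        pub_pos = 0
        for rec, flag in zip(fresh, flags):
            if flag:
                c = min(int(counts_batch[pub_pos]), n)
                pub_pos += 1
                remaining = total_slots - slots_used
                if remaining < 2:
                    privates.append(rec)
                    slots_used += 1
                else:
                    c = min(c, remaining)
                    publics.append(rec)
                    public_counts.append(c)
                    slots_used += c
            else:
                privates.append(rec)
                slots_used += 1
            if slots_used >= total_slots:
                break

    # Phase B: place publics, largest counts first, each into the c
    # repertoires with greatest remaining capacity (random tie-break).
    # Max-capacity-first placement never strands capacity, so every public
    # sequence receives its full drawn count; with private slots providing
    # slack, ties dominate and the choice is effectively uniform.
    capacity = depths.copy()
    reps_members: list[list[Receptor]] = [[] for _ in range(n)]
    order = np.argsort(public_counts)[::-1]
    demoted = 0
    for oi in order:
        rec, c = publics[oi], public_counts[oi]
        nz = np.flatnonzero(capacity > 0)
        if nz.size < 2:
            demoted += 1
            privates.append(rec)
            continue
        c = min(c, nz.size)
        if nz.size == c:
            chosen = nz
        else:
            kth = np.partition(capacity, n - c)[n - c]  # c-th largest capacity
            above = np.flatnonzero(capacity > kth)
            ties = np.flatnonzero(capacity == kth)
            need = c - above.size
            chosen = (
                above if need == 0
                else np.concatenate([above, rng.choice(ties, size=need, replace=False)])
            )
        for r_idx in chosen:
            reps_members[r_idx].append(rec)
        capacity[chosen] -= 1
    if demoted:
        logger.info("public correction: %d sequences demoted to private at end-game", demoted)
    # privates fill what's left, in generation order
    slots_left = int(capacity.sum())
    while len(privates) < slots_left:
        privates.extend(
            _sample_unique_list(engine, slots_left - len(privates), rng, seen)
        )
    fill = np.repeat(np.arange(n), capacity)
    for rec, r_idx in zip(privates, fill):
        reps_members[r_idx].append(rec)

    reps = [
        Repertoire(f"rep_{i:05d}", None, set(reps_members[i])) for i in range(n)
    ]
    n_unique = len({r for rep in reps for r in rep.receptors})
    return RepertoireDataset(
        reps,
        provenance={
            "stage": "public_correction",
            "config": config.semantic_dict(),
            "config_hash": config.config_hash(),
            "n_public": len(publics) - demoted,
            "n_unique": n_unique,
        },
    )


# -- stage iv: signal implantation -----------------------------------------

def _assign_labels(
    dataset: RepertoireDataset, config: SimConfig, rng: np.random.Generator
) -> RepertoireDataset:
    n = dataset.n_repertoires
    pos_idx = set(rng.choice(n, size=config.n_positive, replace=False).tolist())
    reps = [
        Repertoire(r.repertoire_id, POSITIVE if i in pos_idx else NEGATIVE,
                   set(r.receptors))
        for i, r in enumerate(dataset.repertoires)
    ]
    return RepertoireDataset(reps, provenance=dict(dataset.provenance))


def _private_slots(dataset: RepertoireDataset) -> dict[str, list[Receptor]]:
    """Per repertoire, its receptors carried by no other repertoire."""
    counts = dataset.occurrence_counts()
    return {
        rep.repertoire_id: [r for r in rep.receptors if counts[r] == 1]
        for rep in dataset.repertoires
    }


def _place_signal(
    rep: Repertoire,
    rec: Receptor,
    private_pool: list[Receptor],
    rng: np.random.Generator,
) -> bool:
    """Replace one private slot of *rep* with *rec*; False if impossible."""
    while private_pool:
        victim = private_pool.pop(int(rng.integers(len(private_pool))))
        if victim in rep.receptors and victim != rec:
            rep.receptors.discard(victim)
            rep.receptors.add(rec)
            return True
    return False


def implant_signals(
    dataset: RepertoireDataset,
    signal_pool: list[Receptor],
    config: SimConfig,
    signal_model: IncidenceModel | None = None,
    rng: np.random.Generator | None = None,
    override_feasibility: bool = False,
) -> RepertoireDataset:
    """Stage iv: label the cohort and implant signal sequences.

    round(positive_fraction x n) repertoires become positive. Pool sequences
    are taken in uniform random order; each receives an incidence count drawn
    from the signal model (denominator: positive repertoire count) and is
    placed into that many distinct positive repertoires, replacing private
    slots so depth is preserved. If the model-drawn counts fall short of the
    witness-rate budget, counts are topped up round-robin toward the
    feasibility caps. Negative repertoires receive no implants and are not
    screened for chance occurrences. Every placement is recorded in the
    manifest. Infeasible configurations raise unless overridden.
    """
    if signal_model is None:
        from .fixtures import default_signal_model

        signal_model = default_signal_model()
    rng = rng if rng is not None else substream(config.seed, "implant")
    if config.witness_rate > 0 and not signal_pool:
        raise ValidationError("witness_rate > 0 requires a non-empty signal pool")
    report = assess_feasibility(signal_pool, config, signal_model) if signal_pool else None
    if report is not None and not report.feasible:
        if not override_feasibility:
            raise FeasibilityError(
                "witness rate infeasible for this signal pool:\n" + report.guidance,
                report,
            )
        logger.warning(
            "OVERRIDE: implanting despite infeasible witness rate; the realized "
            "witness rate will fall short.\n%s", report.guidance
        )

    labeled = _assign_labels(dataset, config, rng)
    positives = [r for r in labeled.repertoires if r.label == POSITIVE]
    n_pos = len(positives)
    required = round_half_up(n_pos * config.witness_rate)
    labeled.provenance.update(
        stage="implanted",
        required_total=required,
        witness_rate=config.witness_rate,
        witness_rate_per_1e5=config.witness_rate_per_1e5,
    )
    if required == 0:
        return labeled

    pool = _pool_used(signal_pool, config)
    caps = {
        ident: min(cap, n_pos) for ident, _, cap in report.per_sequence_caps
    }
    order = list(rng.permutation(len(pool)))
    counts: dict[int, int] = {}
    total = 0
    for pi in order:
        if total >= required:
            break
        rec = pool[pi]
        cap = caps[rec.identity]
        if cap < 2:
            continue
        c = sample_incidence_count(signal_model, rec.pgen, n_pos, rng)
        c = min(c, cap)
        remaining = required - total
        if c > remaining:
            c = max(2, remaining)
        counts[pi] = c
        total += c
    # top up toward caps if the model draws fell short of the budget
    topped = 0
    while total < required:
        movable = [pi for pi, c in counts.items() if c < caps[pool[pi].identity]]
        fresh = [pi for pi in order if pi not in counts and caps[pool[pi].identity] >= 2]
        if not movable and not fresh:
            break
        if fresh and (total + 2 <= required or not movable):
            pi = fresh[0]
            counts[pi] = 2
            total += 2
            topped += 2
            continue
        rng.shuffle(movable)
        for pi in movable:
            if total >= required:
                break
            counts[pi] += 1
            total += 1
            topped += 1
    if topped:
        logger.info("implantation: topped up %d instances toward caps", topped)
    labeled.provenance["implant_topped_up"] = topped

    private_pools = {
        rid: lst for rid, lst in _private_slots(labeled).items()
    }
    manifest: list[tuple[Receptor, str]] = []
    realized = 0
    for pi, c in counts.items():
        rec = pool[pi]
        candidates = [rep for rep in positives if rec not in rep.receptors]
        if len(candidates) < c:
            logger.info(
                "signal %s already present by chance in %d repertoires; reducing "
                "placements", rec.identity, c - len(candidates)
            )
            c = len(candidates)
        chosen = rng.choice(len(candidates), size=c, replace=False)
        for ci in chosen:
            rep = candidates[int(ci)]
            if _place_signal(rep, rec, private_pools[rep.repertoire_id], rng):
                manifest.append((rec, rep.repertoire_id))
                realized += 1
    labeled.manifest = manifest
    labeled.provenance["realized_total"] = realized
    low = (1 - WITNESS_TOTAL_TOLERANCE) * required
    if report.feasible and realized < low:
        logger.warning(
            "realized signal total %d below tolerance band around %d", realized, required
        )
    return RepertoireDataset(labeled.repertoires, manifest, labeled.provenance)


def naive_implant(
    dataset: RepertoireDataset,
    signal_pool: list[Receptor],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> RepertoireDataset:
    """Uniform signal implantation ignoring incidence models (the biased contrast).

    Each positive repertoire receives round(witness_rate) signal sequences
    drawn uniformly from the pool — the intuitive recipe whose implants are
    the cohort's only outliers.
    """
    rng = rng if rng is not None else substream(config.seed, "naive_implant")
    labeled = _assign_labels(dataset, config, rng)
    labeled.provenance.update(stage="naive_implanted", witness_rate=config.witness_rate)
    per_rep = round_half_up(config.witness_rate)
    if per_rep == 0:
        return labeled
    pool = _pool_used(signal_pool, config)
    if per_rep > len(pool):
        raise ValidationError(
            f"witness rate {config.witness_rate} exceeds pool size {len(pool)}"
        )
    private_pools = _private_slots(labeled)
    manifest: list[tuple[Receptor, str]] = []
    for rep in labeled.repertoires:
        if rep.label != POSITIVE:
            continue
        chosen = rng.choice(len(pool), size=per_rep, replace=False)
        for ci in chosen:
            rec = pool[int(ci)]
            if rec in rep.receptors:
                continue
            if _place_signal(rep, rec, private_pools[rep.repertoire_id], rng):
                manifest.append((rec, rep.repertoire_id))
    return RepertoireDataset(labeled.repertoires, manifest, labeled.provenance)


# -- workflow orchestration ------------------------------------------------

WORKFLOW_MODES = ("feasibility", "baseline", "public_correction", "full")


def run_workflow(
    config: SimConfig,
    mode: str,
    out_dir,
    signal_pool: list[Receptor] | None = None,
    signal_model: IncidenceModel | None = None,
    public_model: IncidenceModel | None = None,
    override_feasibility: bool = False,
):
    """Run the pipeline end-to-end or stage-by-stage, writing artifacts.

    mode "feasibility" writes the report JSON; "baseline" and
    "public_correction" write their stage's cohort; "full" chains
    feasibility -> public correction -> implantation and writes the labeled
    cohort with manifest. Every run writes a provenance log (config hash,
    seed, stage timings).
    """
    from pathlib import Path

    from . import io as _io
    from .fixtures import default_public_model, default_signal_model

    if mode not in WORKFLOW_MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {WORKFLOW_MODES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    provenance = {
        "config": config.semantic_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": mode,
        "stage_timings_s": timings,
    }
    needs_signal = mode in ("feasibility", "full") and config.witness_rate > 0
    if needs_signal and signal_pool is None:
        raise ValidationError(
            f"mode {mode!r} with witness_rate > 0 requires a signal pool; "
            "supply one (missing artifact: signal pool TSV)"
        )
    signal_model = signal_model or default_signal_model()
    public_model = public_model or default_public_model()

    result = None
    if mode in ("feasibility", "full") and config.witness_rate > 0:
        t0 = time.perf_counter()
        report = assess_feasibility(signal_pool, config, signal_model)
        timings["feasibility"] = time.perf_counter() - t0
        _io.write_feasibility_report(report, out / "feasibility.json")
        if mode == "feasibility":
            result = report
        elif not report.feasible and not override_feasibility:
            _io.write_json(provenance, out / "provenance.json")
            raise FeasibilityError(
                "witness rate infeasible:\n" + report.guidance, report
            )
    if mode == "baseline":
        t0 = time.perf_counter()
        ds = generate_baseline(config)
        timings["baseline"] = time.perf_counter() - t0
        _io.write_dataset(ds, out)
        result = ds
    if mode in ("public_correction", "full"):
        t0 = time.perf_counter()
        ds = correct_public_component(config, public_model=public_model)
        timings["public_correction"] = time.perf_counter() - t0
        if mode == "full":
            t0 = time.perf_counter()
            ds = implant_signals(
                ds, signal_pool or [], config, signal_model,
                override_feasibility=override_feasibility,
            )
            timings["implantation"] = time.perf_counter() - t0
        _io.write_dataset(ds, out)
        result = ds
    _io.write_json(provenance, out / "provenance.json")
    return result
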