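"""Reference sequence pools and pattern queries.

Signal pools are built by generating a large reference set of receptors once,
then querying it for sequences that already carry patterns of interest
(contiguous amino-acid k-mers, optionally restricted by gene usage). This
selects naturally occurring sequences instead of implanting motifs into
existing ones — implantation perturbs positional and compositional biases and
is itself a shortcut-learning hazard, so it is deliberately not offered.

Matching is plain substring containment anywhere in the junction (grep
semantics); overlapping hits within one sequence count once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engines import Engine, get_engine
from .errors import ValidationError
from .receptors import Receptor, is_valid_junction
from .rng import substream


@dataclass(frozen=True)
class PatternQuery:
    """Contiguous-substring patterns plus optional gene constraints.

    ``match_mode="any"`` (default) keeps receptors containing at least one
    pattern; ``"all"`` requires every pattern. ``v_calls``/``j_calls``, when
    given, intersect the pattern matches.
    """

    patterns: tuple[str, ...]
    match_mode: str = "any"
    v_calls: tuple[str, ...] | None = None
    j_calls: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "patterns", tuple(self.patterns))
        if not self.patterns:
            raise ValidationError("query needs at least one pattern")
        for p in self.patterns:
            if not is_valid_junction(p):
                raise ValidationError(f"invalid pattern characters in {p!r}")
        if self.match_mode not in ("any", "all"):
            raise ValidationError(f"match_mode must be 'any' or 'all': {self.match_mode!r}")
        if self.v_calls is not None:
            object.__setattr__(self, "v_calls", tuple(self.v_calls))
        if self.j_calls is not None:
            object.__setattr__(self, "j_calls", tuple(self.j_calls))


def build_reference_pool(
    engine: Engine | str,
    n: int,
    rng: np.random.Generator | int = 0,
    path=None,
) -> list[Receptor]:
    """Generate *n* receptors and keep the unique ones, each with pgen.

    The pool is returned in first-generation order; pass *path* to persist
    it as TSV (via :func:`airrshare.io.write_pool_tsv`) so it can be queried
    many times without regeneration.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    engine = get_engine(engine)
    if isinstance(rng, (int, np.integer)):
        rng = substream(int(rng), "reference_pool")
    seen: dict[tuple, Receptor] = {}
    for rec in engine.sample(n, rng):
        if rec.identity not in seen:
            seen[rec.identity] = rec
    pool = list(seen.values())
    if path is not None:
        from .io import write_pool_tsv

        write_pool_tsv(pool, path)
    return pool


def _matches(rec: Receptor, query: PatternQuery) -> bool:
    if query.v_calls is not None and rec.v_call not in query.v_calls:
        return False
    if query.j_calls is not None and rec.j_call not in query.j_calls:
        return False
    hits = (p in rec.junction_aa for p in query.patterns)
    return any(hits) if query.match_mode == "any" else all(
        p in rec.junction_aa for p in query.patterns
    )


def match_patterns(pool: list[Receptor], query: PatternQuery) -> list[Receptor]:
    """Receptors of *pool* matching *query*, in pool order; no modification."""
    if not pool:
        raise ValidationError("pool is empty")
    return [rec for rec in pool if _matches(rec, query)]
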