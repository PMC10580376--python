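"""Receptor generation engines.

The simulator only needs two capabilities from a generator: draw i.i.d.
receptors annotated with generation probabilities, and compute the
generation probability of a given receptor. The built-in toy engine
provides both with exact arithmetic; the adapter for an external published
V(D)J recombination engine (OLGA) provides the same contract for the four
default recombination models (humanTRB, humanTRA, humanIGH, mouseIGH) when
that engine is installed. Everything downstream is agnostic to the provider.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from .errors import ConfigurationError, EngineUnavailableError
from .receptors import Receptor
from .toy_model import (
    ToyGenerativeModel,
    default_toy_model,
    exact_pgen,
    model_from_yaml,
    sample_arrays,
    sample_receptors,
)

OLGA_DEFAULT_MODELS = ("humanTRB", "humanTRA", "humanIGH", "mouseIGH")


@runtime_checkable
class Engine(Protocol):
    """Contract every generation engine satisfies."""

    def sample(self, n: int, rng: np.random.Generator) -> list[Receptor]:
        """Draw n i.i.d. receptors, each with pgen set."""
        ...

    def pgen(self, receptor: Receptor) -> float:
        """Generation probability of one receptor."""
        ...


class ToyEngine:
    """Engine view over a :class:`ToyGenerativeModel`."""

    def __init__(self, model: ToyGenerativeModel | None = None):
        self.model = model if model is not None else default_toy_model()

    def sample(self, n: int, rng: np.random.Generator) -> list[Receptor]:
        return sample_receptors(self.model, n, rng)

    def sample_arrays(self, n: int, rng: np.random.Generator):
        """Array-level sampling used by the simulator's hot paths."""
        return sample_arrays(self.model, n, rng)

    def pgen(self, receptor: Receptor) -> float:
        return exact_pgen(self.model, receptor)


class OlgaEngine:
    """Adapter around the OLGA V(D)J recombination engine.

    Requires the optional ``olga`` dependency; only OLGA's bundled default
    models are accepted. Sequences are exchanged as
    (junction_aa, v_call, j_call) triples and pgen is computed with both
    gene masks applied.
    """

    def __init__(self, model_name: str):
        if model_name not in OLGA_DEFAULT_MODELS:
            raise ConfigurationError(
                f"unsupported recombination model {model_name!r}; "
                f"choose one of {OLGA_DEFAULT_MODELS}"
            )
        try:
            import olga.load_model as load_model
            import olga.generation_probability as gp
            import olga.sequence_generation as sg
            import olga
        except ImportError as exc:
            raise EngineUnavailableError(
                "the external V(D)J engine 'olga' is not installed; "
                "install it (pip install olga) to use model "
                f"{model_name!r}, or use the built-in toy engine"
            ) from exc
        import os

        self.model_name = model_name
        chain = "heavy_chain" if model_name.endswith("IGH") else (
            "light_chain" if model_name == "humanTRA" else "heavy_chain"
        )
        vdj = model_name not in ("humanTRA",)
        base = os.path.join(os.path.dirname(olga.__file__), "default_models", model_name)
        params = os.path.join(base, "model_params.txt")
        marginals = os.path.join(base, "model_marginals.txt")
        v_anchor = os.path.join(base, "V_gene_CDR3_anchors.csv")
        j_anchor = os.path.join(base, "J_gene_CDR3_anchors.csv")
        if vdj:
            genomic = load_model.GenomicDataVDJ()
            genomic.load_igor_genomic_data(params, v_anchor, j_anchor)
            generative = load_model.GenerativeModelVDJ()
            generative.load_and_process_igor_model(marginals)
            self._gen = sg.SequenceGenerationVDJ(generative, genomic)
            self._pgen = gp.GenerationProbabilityVDJ(generative, genomic)
        else:
            genomic = load_model.GenomicDataVJ()
            genomic.load_igor_genomic_data(params, v_anchor, j_anchor)
            generative = load_model.GenerativeModelVJ()
            generative.load_and_process_igor_model(marginals)
            self._gen = sg.SequenceGenerationVJ(generative, genomic)
            self._pgen = gp.GenerationProbabilityVJ(generative, genomic)
        self._genomic = genomic

    def sample(self, n: int, rng: np.random.Generator) -> list[Receptor]:
        import random as _random

        _random.seed(int(rng.integers(0, 2**31 - 1)))
        out = []
        for _ in range(n):
            _, aa, v_in, j_in = self._gen.gen_rnd_prod_CDR3()
            v_call = self._genomic.genV[v_in][0]
            j_call = self._genomic.genJ[j_in][0]
            rec = Receptor(aa, v_call, j_call)
            out.append(rec.with_pgen(self.pgen(rec)))
        return out

    def pgen(self, receptor: Receptor) -> float:
        return float(
            self._pgen.compute_aa_CDR3_pgen(
                receptor.junction_aa, receptor.v_call, receptor.j_call
            )
        )


def get_engine(spec: str | Engine | ToyGenerativeModel = "toy") -> Engine:
    """Resolve an engine specification.

    ``"toy"`` gives the default toy engine; a path ending in .yaml/.yml
    loads a toy model spec; one of the external engine's default model names
    dispatches to the adapter; an object already satisfying the engine
    contract is passed through.
    """
    if isinstance(spec, ToyGenerativeModel):
        return ToyEngine(spec)
    if not isinstance(spec, str):
        if isinstance(spec, Engine):
            return spec
        raise ConfigurationError(f"object does not satisfy the engine contract: {spec!r}")
    if spec == "toy":
        return ToyEngine()
    if spec.endswith((".yaml", ".yml")):
        return ToyEngine(model_from_yaml(spec))
    if spec in OLGA_DEFAULT_MODELS:
        return OlgaEngine(spec)
    raise ConfigurationError(
        f"unknown engine spec {spec!r}; expected 'toy', a toy-model YAML path, "
        f"or one of {OLGA_DEFAULT_MODELS}"
    )
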