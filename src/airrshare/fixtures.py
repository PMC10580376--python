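"""Bundled synthetic incidence models.

These are NOT calibrated on any experimental cohort: they are synthetic
fixtures whose shapes mimic what calibration on an antigen-experienced TCRbeta
cohort produces — most public sequences shared by under 2% of the cohort with
a small highly shared tail, and signal sequences shared more widely but never
by more than 30% of the sample. Users simulating for production benchmarks
should calibrate their own models (see :func:`airrshare.incidence.calibrate`)
on an experimental dataset of the locus and species they care about.
"""

from __future__ import annotations

from importlib.resources import files

from .incidence import IncidenceModel, load_model

_DATA = files("airrshare.data")


def default_signal_model() -> IncidenceModel:
    """Synthetic signal-component incidence model (max incidence 30%)."""
    return load_model(str(_DATA / "synthetic_signal_incidence.json"))


def default_public_model() -> IncidenceModel:
    """Synthetic public-component incidence model (Zipf-like sharing tail)."""
    return load_model(str(_DATA / "synthetic_public_incidence.json"))
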