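"""File formats: AIRR Rearrangement TSV repertoires, metadata, manifests,
pools, feasibility reports, audit outputs, and the YAML run configuration.

One repertoire per AIRR Rearrangement TSV file with columns ``junction_aa``,
``v_call``, ``j_call`` (``pgen`` carried as an extra column when known;
``duplicate_count`` written as 1 — clonal frequencies are not simulated).
The junction is the amino-acid junction including the conserved flanks
exactly as the engine produced it; no trimming is applied. Labels serialize
as "positive"/"negative"; numeric 1/0 are accepted on read. All writers emit
deterministically ordered rows so equal datasets produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dataset import NEGATIVE, POSITIVE, Repertoire, RepertoireDataset
from .errors import SchemaError, ValidationError
from .receptors import Receptor, is_valid_junction

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("junction_aa", "v_call", "j_call")

_LABEL_ALIASES = {
    "positive": POSITIVE, "negative": NEGATIVE,
    "1": POSITIVE, "0": NEGATIVE, 1: POSITIVE, 0: NEGATIVE,
    True: POSITIVE, False: NEGATIVE,
}


def _require_columns(df: pd.DataFrame, path, columns=REQUIRED_COLUMNS) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_repertoire_tsv(path) -> set[Receptor]:
    """Read one repertoire; duplicate rows collapse with a logged count."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, path)
    bad = [
        i + 2  # 1-based line numbers counting the header
        for i, j in enumerate(df["junction_aa"]) if not is_valid_junction(j)
    ]
    if bad:
        raise SchemaError(
            f"{path}: malformed junction_aa on line(s) {bad[:20]}"
            + (" ..." if len(bad) > 20 else "")
        )
    pgen = pd.to_numeric(df["pgen"], errors="coerce") if "pgen" in df.columns else None
    out: set[Receptor] = set()
    for i in range(len(df)):
        p = None
        if pgen is not None and pd.notna(pgen.iloc[i]):
            p = float(pgen.iloc[i])
        out.add(Receptor(df["junction_aa"].iloc[i], df["v_call"].iloc[i],
                         df["j_call"].iloc[i], p))
    dropped = len(df) - len(out)
    if dropped:
        logger.warning("%s: collapsed %d duplicate rows", path, dropped)
    return out


def write_repertoire_tsv(receptors, path) -> None:
    recs = sorted(receptors, key=lambda r: r.identity)
    df = pd.DataFrame(
        {
            "junction_aa": [r.junction_aa for r in recs],
            "v_call": [r.v_call for r in recs],
            "j_call": [r.j_call for r in recs],
            "duplicate_count": 1,
            "pgen": [("" if r.pgen is None else repr(r.pgen)) for r in recs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read the cohort metadata table (repertoire_id, filename, label)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, path, ("repertoire_id", "filename", "label"))
    labels = []
    for raw in df["label"]:
        if raw == "":
            labels.append(None)
            continue
        norm = _LABEL_ALIASES.get(raw, _LABEL_ALIASES.get(raw.strip().lower()))
        if norm is None:
            raise ValidationError(
                f"{path}: label {raw!r} outside the binary set "
                f"{{positive, negative, 1, 0}}"
            )
        labels.append(norm)
    df = df.assign(label=labels)
    if df["repertoire_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate repertoire_id values")
    return df


def write_manifest(manifest, path) -> None:
    rows = sorted(
        (rec.identity + (rep_id,)) for rec, rep_id in manifest
    )
    df = pd.DataFrame(
        rows, columns=["junction_aa", "v_call", "j_call", "repertoire_id"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> list[tuple[tuple[str, str, str], str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, path, ("junction_aa", "v_call", "j_call", "repertoire_id"))
    return [
        ((row.junction_aa, row.v_call, row.j_call), row.repertoire_id)
        for row in df.itertuples()
    ]


def write_pool_tsv(pool, path) -> None:
    df = pd.DataFrame(
        {
            "junction_aa": [r.junction_aa for r in pool],
            "v_call": [r.v_call for r in pool],
            "j_call": [r.j_call for r in pool],
            "pgen": [("" if r.pgen is None else repr(r.pgen)) for r in pool],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pool_tsv(path) -> list[Receptor]:
    """Read a sequence pool; order preserved, duplicates collapsed."""
    df = pd.read_csv(path, sep="\t", dtype={"junction_aa": str, "v_call": str, "j_call": str})
    _require_columns(df, path)
    out, seen = [], set()
    has_pgen = "pgen" in df.columns
    for row in df.itertuples():
        key = (row.junction_aa, row.v_call, row.j_call)
        if key in seen:
            continue
        seen.add(key)
        p = float(row.pgen) if has_pgen and pd.notna(row.pgen) else None
        out.append(Receptor(key[0], key[1], key[2], p))
    return out


# -- whole-dataset round trip ----------------------------------------------

def write_dataset(dataset: RepertoireDataset, out_dir) -> None:
    """Write repertoire TSVs, metadata, manifest and provenance to *out_dir*."""
    out = Path(out_dir)
    rep_dir = out / "repertoires"
    rep_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for rep in dataset.repertoires:
        fname = f"{rep.repertoire_id}.tsv"
        write_repertoire_tsv(rep.receptors, rep_dir / fname)
        meta_rows.append(
            {"repertoire_id": rep.repertoire_id,
             "filename": f"repertoires/{fname}",
             "label": rep.label if rep.label is not None else ""}
        )
    pd.DataFrame(meta_rows).to_csv(out / "metadata.tsv", sep="\t", index=False)
    write_manifest(dataset.manifest, out / "manifest.tsv")
    if dataset.provenance:
        write_json(dataset.provenance, out / "dataset_provenance.json")


def read_dataset(in_dir) -> RepertoireDataset:
    """Load a dataset written by :func:`write_dataset`; fails fast on
    metadata rows whose repertoire file is missing."""
    base = Path(in_dir)
    meta = read_metadata(base / "metadata.tsv")
    missing = [f for f in meta["filename"] if not (base / f).exists()]
    if missing:
        raise ValidationError(
            f"metadata references missing repertoire files: {missing[:5]}"
        )
    reps = [
        Repertoire(row.repertoire_id,
                   row.label if row.label else None,
                   read_repertoire_tsv(base / row.filename))
        for row in meta.itertuples()
    ]
    manifest = []
    man_path = base / "manifest.tsv"
    if man_path.exists():
        by_identity = {}
        for rep in reps:
            for rec in rep.receptors:
                by_identity.setdefault(rec.identity, rec)
        for ident, rep_id in read_manifest(man_path):
            manifest.append((by_identity.get(ident, Receptor(*ident)), rep_id))
    provenance = {}
    prov_path = base / "dataset_provenance.json"
    if prov_path.exists():
        provenance = json.loads(prov_path.read_text())
    return RepertoireDataset(reps, manifest, provenance)


# -- reports ---------------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=str) + "\n")


def write_feasibility_report(report, path) -> None:
    write_json(report.to_dict(), path)


def write_audit_tsv(result, path) -> None:
    """One row per public sequence, highest outlier scores first."""
    pd.DataFrame(result.to_rows()).to_csv(path, sep="\t", index=False)


def write_audit_summary(result, thresholds, truth, path) -> None:
    from .audit import threshold_precision_recall

    summary = {
        "n_public_sequences": len(result.records),
        "n_trials": result.n_trials,
        "n_repertoires_denominator": result.n_repertoires,
        "n_positive": result.n_positive,
        "n_negative": result.n_negative,
        "denominator": result.denominator,
        "thresholds": {},
    }
    for t in thresholds:
        pr = threshold_precision_recall(result.records, truth, t)
        summary["thresholds"][str(t)] = {
            "precision": pr.precision, "recall": pr.recall,
            "tp": pr.tp, "fp": pr.fp, "fn": pr.fn,
            "n_calls": pr.n_calls, "truth_empty": pr.truth_empty,
        }
    write_json(summary, path)


# -- run configuration -----------------------------------------------------

_RUN_CONFIG_KEYS = {
    "n_repertoires", "depth", "positive_fraction", "depth_spread",
    "public_fraction", "witness_rate", "n_signal_pool_used", "engine", "seed",
    "mode", "signal_pool", "signal_model", "public_model", "out_dir",
    "audit_thresholds", "override_feasibility", "schema_version",
}


@dataclass
class RunConfig:
    """Everything a workflow run needs: simulation parameters plus paths."""

    sim: "SimConfig"  # noqa: F821 - resolved at runtime
    mode: str = "full"
    signal_pool: str | None = None
    signal_model: str | None = None
    public_model: str | None = None
    out_dir: str | None = None
    audit_thresholds: tuple = (35.0,)
    override_feasibility: bool = False
    schema_version: int = 1


def load_run_config(path) -> RunConfig:
    """Load and validate the YAML run configuration; unknown keys rejected
    and every referenced path checked before any stage runs."""
    from .simulate import SimConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(raw) - _RUN_CONFIG_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    if raw.get("schema_version", 1) != 1:
        raise ValidationError(f"{path}: unsupported schema_version")
    sim_keys = {
        k: raw[k] for k in (
            "n_repertoires", "depth", "positive_fraction", "depth_spread",
            "public_fraction", "witness_rate", "n_signal_pool_used",
            "engine", "seed",
        ) if k in raw
    }
    try:
        sim = SimConfig(**sim_keys)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    cfg = RunConfig(
        sim=sim,
        mode=raw.get("mode", "full"),
        signal_pool=raw.get("signal_pool"),
        signal_model=raw.get("signal_model"),
        public_model=raw.get("public_model"),
        out_dir=raw.get("out_dir"),
        audit_thresholds=tuple(raw.get("audit_thresholds", (35.0,))),
        override_feasibility=bool(raw.get("override_feasibility", False)),
    )
    base = Path(path).parent
    for attr in ("signal_pool", "signal_model", "public_model"):
        p = getattr(cfg, attr)
        if p is not None:
            resolved = Path(p) if Path(p).is_absolute() else base / p
            if not resolved.exists():
                raise ValidationError(f"{path}: {attr} file not found: {p}")
            setattr(cfg, attr, str(resolved))
    return cfg
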