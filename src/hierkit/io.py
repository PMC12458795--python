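"""Readers/writers for the package's on-disk formats, plus run manifests.

Formats: contest logs and tidy result tables as CSV; traces as CSV with an
event sidecar; count matrices as Matrix Market (MTX) with genes/barcodes/
labels TSVs; gene-set collections as GMT.  Every CLI run writes a JSON
manifest naming its inputs, parameters and seed so outputs are reproducible
bit-for-bit for deterministic stages.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csc_matrix

from hierkit.gsea import CountMatrix, GeneSetCollection
from hierkit.synthio import CONTEST_COLUMNS, TraceSet

__all__ = [
    "read_contest_log",
    "write_contest_log",
    "read_trace",
    "write_trace",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "write_manifest",
]


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# contest logs
# ---------------------------------------------------------------------------


def read_contest_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, [c for c in CONTEST_COLUMNS if not c.endswith("_s")], path)
    return df


def write_contest_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_trace(trace: TraceSet, path, events_path=None) -> None:
    """Trace as (time_s, value) CSV plus an (event, time_s) sidecar."""
    pd.DataFrame({"time_s": trace.time, "value": trace.values}).to_csv(path, index=False)
    if events_path is None:
        events_path = Path(path).with_suffix(".events.csv")
    pd.DataFrame(
        {"event": list(trace.events), "time_s": list(trace.events.values())}
    ).to_csv(events_path, index=False)


def read_trace(path, events_path=None, baseline_window_s: float = 30.0) -> TraceSet:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "value"], path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise SchemaError(f"{path}: need at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    events = {}
    if events_path is None:
        candidate = Path(path).with_suffix(".events.csv")
        events_path = candidate if candidate.exists() else None
    if events_path is not None:
        ev = pd.read_csv(events_path)
        _require_columns(ev, ["event", "time_s"], events_path)
        events = dict(zip(ev["event"], ev["time_s"].astype(float)))
    return TraceSet(values=df["value"].to_numpy(float), fs=fs, events=events,
                    baseline_window_s=baseline_window_s)


# ---------------------------------------------------------------------------
# count matrices (MTX + TSV sidecars)
# ---------------------------------------------------------------------------


def write_counts(cm: CountMatrix, directory) -> None:
    """Matrix Market counts plus genes.tsv / barcodes.tsv / labels.tsv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mmwrite(d / "matrix.mtx", csc_matrix(cm.counts))
    pd.Series(cm.genes).to_csv(d / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.barcodes).to_csv(d / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.DataFrame(
        {"barcode": cm.barcodes, "condition": cm.condition, "cluster": cm.cluster}
    ).to_csv(d / "labels.tsv", sep="\t", index=False)


def read_counts(directory) -> CountMatrix:
    d = Path(directory)
    counts = np.asarray(mmread(d / "matrix.mtx").todense())
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    labels = pd.read_csv(d / "labels.tsv", sep="\t")
    _require_columns(labels, ["barcode", "condition", "cluster"], d / "labels.tsv")
    labels = labels.set_index("barcode").loc[barcodes]
    return CountMatrix(
        counts=counts.astype(int),
        genes=genes,
        barcodes=barcodes,
        condition=labels["condition"].to_numpy(object),
        cluster=labels["cluster"].to_numpy(object),
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path, min_size: int = 15, max_size: int = 500) -> GeneSetCollection:
    """GMT: one set per line, tab-separated: name, description, genes..."""
    sets = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{line_no}: GMT lines need name, description, >=1 gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets, min_size=min_size, max_size=max_size)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def write_manifest(path, command: str, inputs: dict, parameters: dict, outputs: list, seed=None) -> None:
    """Record what produced a set of outputs (inputs, parameters, seed, versions)."""
    import hierkit

    manifest = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": parameters,
        "outputs": [str(o) for o in outputs],
        "seed": seed,
        "versions": {"hierkit": hierkit.__version__, "python": platform.python_version()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
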