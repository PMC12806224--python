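"""File formats: FASTA corpora, task TSVs, YAML run configs, HDF5 checkpoints.

TSV dialect for tasks: tab-separated, UTF-8, header required. Columns:
``sequence`` plus ``label`` (protein-level scalar or class) or ``labels``
(residue-level digit string of equal length), optional ``split``
(train/valid/test; defaults to train). Parsers reject malformed input with
the offending row or line number rather than coercing silently.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tasks import TaskSpec, TaskRecord, TaskDataset

logger = logging.getLogger("prothyena")

__all__ = ["read_fasta", "write_fasta", "read_task_tsv", "write_task_tsv",
           "load_run_config", "save_checkpoint", "load_checkpoint"]


# ---------------------------------------------------------------------- FASTA

def read_fasta(path) -> list:
    """Parse a (possibly line-wrapped, mixed-case, CRLF) FASTA file.

    Returns ordered (id, sequence) pairs. Duplicate ids are kept, with a
    logged warning. A sequence line before any header is a parse error.
    """
    path = Path(path)
    with open(path, "r", newline=None) as fh:
        first = fh.readline()
        while first and not first.strip():
            first = fh.readline()
        if first and not first.startswith(">"):
            raise ValueError(
                f"{path}:1: sequence data before the first FASTA header")
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    ids = [rid for rid, _ in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        logger.warning("duplicate FASTA ids kept: %s", sorted(dupes))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="")
            for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ------------------------------------------------------------------- task TSV

def read_task_tsv(path, spec: TaskSpec) -> TaskDataset:
    """Read a labeled task file and validate it against the task spec."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    label_col = "labels" if spec.resolution == "residue" else "label"
    for col in ("sequence", label_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "split" not in df.columns:
        logger.info("%s: no split column; all rows default to train", path)
        df["split"] = "train"
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        seq = getattr(row, "sequence")
        raw = getattr(row, label_col)
        if not isinstance(seq, str) or not seq:
            raise ValueError(f"{path}: row {row_no}: empty sequence")
        if spec.resolution == "residue":
            if not isinstance(raw, str) or len(raw) != len(seq):
                raise ValueError(
                    f"{path}: row {row_no}: residue label string length "
                    f"does not match sequence length {len(seq)}")
            label = raw
        elif spec.task_type == "regression":
            label = float(raw)
        else:
            label = int(raw)
        records.append(TaskRecord(seq, label, str(getattr(row, "split"))))
    return TaskDataset(spec, records).validate()


def write_task_tsv(dataset: TaskDataset, path) -> None:
    label_col = "labels" if dataset.spec.resolution == "residue" else "label"
    df = pd.DataFrame({
        "sequence": [r.sequence for r in dataset.records],
        label_col: [r.label for r in dataset.records],
        "split": [r.split for r in dataset.records],
    })
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- run configs

_KNOWN_SECTIONS = {"model", "train", "task", "paths", "seed", "kind"}


def load_run_config(path) -> dict:
    """Load a YAML run config, rejecting unknown top-level keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(model, path, config: dict | None = None) -> None:
    """Write named parameters (and the model config) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("params")
        for name, p in model.named_parameters():
            grp.create_dataset(name, data=p.data)
        cfg = config if config is not None else \
            getattr(model, "config", None) and model.config.to_dict()
        if cfg:
            f.attrs["config"] = yaml.safe_dump(cfg)
        f.attrs["kind"] = type(model).__name__


def load_checkpoint(model, path) -> None:
    """Load parameters into ``model`` in place; shapes must match exactly."""
    with h5py.File(path, "r") as f:
        grp = f["params"]
        names = {name for name, _ in model.named_parameters()}
        stored = set(grp.keys())
        if names != stored:
            raise ValueError(
                f"checkpoint mismatch: missing {sorted(names - stored)}, "
                f"unexpected {sorted(stored - names)}")
        for name, p in model.named_parameters():
            data = np.asarray(grp[name])
            if data.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = data.astype(np.float64)


def read_checkpoint_config(path) -> dict:
    with h5py.File(path, "r") as f:
        raw = f.attrs.get("config")
        return yaml.safe_load(raw) if raw else {}
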