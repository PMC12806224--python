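"""Downstream-task containers: task specifications and labeled datasets."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["TaskSpec", "TaskRecord", "TaskDataset"]

TASK_TYPES = ("binary", "multiclass", "regression")
RESOLUTIONS = ("residue", "protein")


@dataclass(frozen=True)
class TaskSpec:
    """What a downstream task predicts and at which resolution.

    ``n_classes`` is 1 for regression, 2 for binary, K for multiclass.
    Residue-resolution regression is not supported (no such task exists in
    the benchmark suite this package emulates).
    """
    task_type: str
    resolution: str = "protein"
    n_classes: int = 2

    def __post_init__(self):
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task type {self.task_type!r}")
        if self.resolution not in RESOLUTIONS:
            raise ValueError(f"unknown resolution {self.resolution!r}")
        if self.task_type == "regression":
            if self.n_classes != 1:
                raise ValueError("regression tasks use n_classes=1")
            if self.resolution == "residue":
                raise ValueError("residue-level regression is not supported")
        elif self.task_type == "binary" and self.n_classes != 2:
            raise ValueError("binary tasks use n_classes=2")
        elif self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")


@dataclass(frozen=True)
class TaskRecord:
    """One labeled sequence.

    ``label`` is a float (regression), an int class (protein-level
    classification), or a string of per-residue digit labels whose length
    equals the sequence length (residue-level).
    """
    sequence: str
    label: object
    split: str = "train"


@dataclass
class TaskDataset:
    spec: TaskSpec
    records: list = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)  # generator side-info

    def validate(self):
        for i, rec in enumerate(self.records):
            if not rec.sequence:
                raise ValueError(f"record {i}: empty sequence")
            if self.spec.resolution == "residue":
                if not isinstance(rec.label, str) or \
                        len(rec.label) != len(rec.sequence):
                    raise ValueError(
                        f"record {i}: residue label string must match "
                        f"sequence length {len(rec.sequence)}")
                if any(int(c) >= self.spec.n_classes for c in rec.label):
                    raise ValueError(f"record {i}: label class out of range")
            elif self.spec.task_type != "regression":
                if not (0 <= int(rec.label) < self.spec.n_classes):
                    raise ValueError(f"record {i}: label class out of range")
        return self

    def split(self, tag: str) -> list:
        return [r for r in self.records if r.split == tag]

    def __len__(self) -> int:
        return len(self.records)
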