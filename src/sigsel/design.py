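"""Study design: line/replicate labels for each sample and its two gametes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StudyDesign:
    """Line/replicate assignment for every sequenced diploid sample.

    Each sample contributes exactly two gametes (the two allele copies of an
    unphased genotype, in arbitrary within-sample order).  Gamete-level label
    arrays are derived, with gametes of sample ``k`` at rows ``2k`` and
    ``2k + 1``.
    """

    samples: tuple[str, ...]
    line: np.ndarray        # per-sample integer codes, 0..n_lines-1
    replicate: np.ndarray   # per-sample integer codes, 0..n_replicates-1
    line_labels: tuple[str, ...] = ()
    replicate_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        line = np.asarray(self.line, dtype=np.int64)
        rep = np.asarray(self.replicate, dtype=np.int64)
        object.__setattr__(self, "line", line)
        object.__setattr__(self, "replicate", rep)
        if len(self.samples) != line.size or line.size != rep.size:
            raise ValueError("samples, line and replicate must have equal length")
        if line.size == 0:
            raise ValueError("design must contain at least one sample")
        if line.min() < 0 or rep.min() < 0:
            raise ValueError("line/replicate codes must be non-negative")
        if not self.line_labels:
            object.__setattr__(
                self, "line_labels", tuple(f"L{i + 1}" for i in range(line.max() + 1))
            )
        if not self.replicate_labels:
            object.__setattr__(
                self,
                "replicate_labels",
                tuple(f"R{j + 1}" for j in range(rep.max() + 1)),
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names in design")

    # -- basic sizes ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_lines(self) -> int:
        return int(self.line.max()) + 1

    @property
    def n_replicates(self) -> int:
        return int(self.replicate.max()) + 1

    @property
    def cell(self) -> np.ndarray:
        """Per-sample (line, replicate) cell code: ``line * n_replicates + rep``."""
        return self.line * self.n_replicates + self.replicate

    @property
    def n_cells(self) -> int:
        return self.n_lines * self.n_replicates

    # -- gamete-level expansion ---------------------------------------------
    @property
    def gamete_sample(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_samples), 2)

    @property
    def gamete_line(self) -> np.ndarray:
        return np.repeat(self.line, 2)

    @property
    def gamete_replicate(self) -> np.ndarray:
        return np.repeat(self.replicate, 2)

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyDesign":
        """Build from a sheet with columns ``sample``, ``line``, ``replicate``."""
        required = {"sample", "line", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design sheet missing columns: {sorted(missing)}")
        line_cat = pd.Categorical(df["line"].astype(str))
        rep_cat = pd.Categorical(df["replicate"].astype(str))
        return cls(
            samples=tuple(df["sample"].astype(str)),
            line=np.asarray(line_cat.codes, dtype=np.int64),
            replicate=np.asarray(rep_cat.codes, dtype=np.int64),
            line_labels=tuple(line_cat.categories),
            replicate_labels=tuple(rep_cat.categories),
        )

    @classmethod
    def read(cls, path) -> "StudyDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": list(self.samples),
                "line": [self.line_labels[i] for i in self.line],
                "replicate": [self.replicate_labels[j] for j in self.replicate],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    # -- views ---------------------------------------------------------------
    def subset(self, sample_idx: np.ndarray) -> "StudyDesign":
        sample_idx = np.asarray(sample_idx)
        line = self.line[sample_idx]
        rep = self.replicate[sample_idx]
        # recode so codes stay dense
        uline = np.unique(line)
        urep = np.unique(rep)
        return StudyDesign(
            samples=tuple(self.samples[i] for i in sample_idx),
            line=np.searchsorted(uline, line),
            replicate=np.searchsorted(urep, rep),
            line_labels=tuple(self.line_labels[i] for i in uline),
            replicate_labels=tuple(self.replicate_labels[j] for j in urep),
        )

    def single_replicate(self, replicate: int) -> tuple["StudyDesign", np.ndarray]:
        """Restrict to one replicate; returns (design, sample indices kept)."""
        keep = np.flatnonzero(self.replicate == replicate)
        if keep.size == 0:
            raise ValueError(f"no samples in replicate code {replicate}")
        return self.subset(keep), keep
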