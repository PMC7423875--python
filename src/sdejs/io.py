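"""Readers and writers: Bonn-style ASCII segment directories, CSV
feature tables, and ranking CSVs.

A Bonn-style corpus is a directory with one subdirectory per group
(A-E, or the original mirror names Z/O/N/F/S), each holding plain-text
segment files with one amplitude value per line — 4097 lines per segment
in the original recordings.  Segments are loaded with the raw per-sample
amplitudes as features; no spectral extraction is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ejs import FeatureMatrix, RankingResult

#: Directory aliases used by public mirrors of the five-group corpus.
GROUP_DIR_ALIASES = {
    "A": ("A", "Z"),
    "B": ("B", "O"),
    "C": ("C", "N"),
    "D": ("D", "F"),
    "E": ("E", "S"),
}

#: Classification tasks over the five groups: (groups, {group: class}).
TASKS = {
    1: (("A", "B"), {"A": 0, "B": 1}),
    2: (("C", "D", "E"), {"C": 0, "D": 1, "E": 2}),
    3: (("A", "B", "C", "D", "E"), {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1}),
}


@dataclass(frozen=True)
class TaskSpec:
    """One of the three benchmark tasks: eyes open vs closed (1),
    three epileptic states (2), healthy vs epileptic (3)."""

    task_id: int

    def __post_init__(self) -> None:
        if self.task_id not in TASKS:
            raise ValueError(f"task_id must be one of {sorted(TASKS)}")

    @property
    def groups(self) -> tuple:
        return TASKS[self.task_id][0]

    @property
    def class_map(self) -> dict:
        return TASKS[self.task_id][1]


@dataclass
class BonnDataset:
    """All loaded segments (features = raw amplitudes) with group tags."""

    segments: FeatureMatrix
    group_labels: list

    @property
    def n_segments(self) -> int:
        return self.segments.n_samples


def _parse_segment(path: Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno} is not numeric: {line!r}"
                ) from None
    return np.asarray(values)


def _resolve_group_dir(root: Path, group: str, dir_map: dict | None) -> Path:
    if dir_map and group in dir_map:
        candidates = (dir_map[group],)
    else:
        candidates = GROUP_DIR_ALIASES.get(group, (group,))
    for name in candidates:
        if (root / name).is_dir():
            return root / name
    raise FileNotFoundError(
        f"no directory for group {group!r} under {root} (tried {candidates})"
    )


def load_bonn_segments(
    root, groups=("A", "B", "C", "D", "E"), dir_map: dict | None = None
) -> BonnDataset:
    """Load segment files for the requested groups.

    Files within each group are read in lexicographic order so the
    dataset is independent of filesystem enumeration order.  All
    segments must have the same length; ragged files raise a format
    error naming the offending file.
    """
    root = Path(root)
    columns, group_labels, sample_ids = [], [], []
    seg_len = None
    ref_file = None
    for group in groups:
        group_dir = _resolve_group_dir(root, group, dir_map)
        files = sorted(p for p in group_dir.iterdir() if p.suffix.lower() == ".txt")
        if not files:
            raise FileNotFoundError(f"group directory {group_dir} has no .txt segments")
        for path in files:
            seg = _parse_segment(path)
            if seg_len is None:
                seg_len, ref_file = seg.size, path
            elif seg.size != seg_len:
                raise ValueError(
                    f"segment length mismatch: {path} has {seg.size} lines "
                    f"but {ref_file} has {seg_len}"
                )
            columns.append(seg)
            group_labels.append(group)
            sample_ids.append(f"{group}/{path.name}")
    segments = FeatureMatrix(
        np.column_stack(columns),
        feature_ids=[f"t{i}" for i in range(seg_len)],
        sample_ids=sample_ids,
    )
    return BonnDataset(segments=segments, group_labels=group_labels)


def build_task(
    dataset: BonnDataset, task: TaskSpec | int
) -> tuple[FeatureMatrix, np.ndarray]:
    """Restrict a loaded dataset to one task's groups and map group tags
    to integer class labels."""
    if isinstance(task, int):
        task = TaskSpec(task)
    tags = np.asarray(dataset.group_labels)
    missing = [g for g in task.groups if g not in tags]
    if missing:
        raise ValueError(f"task {task.task_id} needs groups {missing} (absent)")
    mask = np.isin(tags, task.groups)
    idx = np.flatnonzero(mask)
    X = dataset.segments.subset_samples(idx)
    labels = np.asarray([task.class_map[g] for g in tags[idx]])
    return X, labels


def load_feature_csv(path, label_column: str | None = None):
    """Read a samples x features CSV with a header row.

    The label column defaults to the last column.  Returns
    ``(FeatureMatrix, labels)`` with features transposed to the package's
    d x n layout.
    """
    df = pd.read_csv(path)
    if label_column is None:
        label_column = df.columns[-1]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not in {path}")
    labels = df[label_column].to_numpy()
    feats = df.drop(columns=[label_column])
    X = FeatureMatrix(
        feats.to_numpy(dtype=float).T,
        feature_ids=list(feats.columns),
        sample_ids=[str(i) for i in df.index],
    )
    return X, labels


def write_feature_csv(path, X: FeatureMatrix, labels) -> None:
    df = pd.DataFrame(X.values.T, columns=X.feature_ids)
    df["label"] = np.asarray(labels)
    df.to_csv(path, index=False)


def write_ranking_csv(path, ranking: RankingResult, feature_ids) -> None:
    """Persist a ranking as ``rank,feature_index,feature_id,score``.

    ``feature_index`` is 0-based, in the package's feature order.
    """
    rows = [
        {
            "rank": r,
            "feature_index": int(i),
            "feature_id": feature_ids[i],
            "score": ranking.scores[i],
        }
        for r, i in enumerate(ranking.order)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ranking_csv(path) -> RankingResult:
    df = pd.read_csv(path).sort_values("rank")
    order = df["feature_index"].to_numpy(dtype=int)
    scores = np.empty(len(order))
    scores[order] = df["score"].to_numpy(dtype=float)
    return RankingResult(scores=scores, order=order)
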