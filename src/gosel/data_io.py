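"""Reading STRING-style networks, GO annotations and protein attributes.

The on-disk dialects are deliberately minimal: per-channel edge-list TSVs
(``protein1  protein2  score``, header optional, gzip accepted, or a combined
file with a ``channel`` column), an annotation TSV with columns
``protein  go_term  evidence  date  aspect``, and a one-identifier-per-line
protein index file.

Dataset assembly follows the CAFA-style temporal holdout: a protein belongs
to train/validation/test according to its earliest annotation date, GO terms
are kept only when supported by enough proteins in every split and not too
generic (more than 5% of the network's proteins), and binary attribute
columns (Pfam domains, subcellular locations) need at least six supporting
proteins.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "EXPERIMENTAL_EVIDENCE_CODES",
    "ProteinIndex",
    "EvidenceNetwork",
    "AnnotationTable",
    "LabelMatrix",
    "AttributeMatrix",
    "EmptyLabelSpaceError",
    "read_string_edges",
    "write_string_edges",
    "temporal_split",
    "onehot_labels",
    "filter_labels",
    "filter_attributes",
    "build_label_matrix",
]

#: STRING evidence channels, in the order they define the feature space.
CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)

#: Evidence codes accepted as experimental support for a GO annotation.
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"IDA", "IPI", "EXP", "IGI", "IMP", "IEP", "IC", "TA"}
)

ASPECTS = ("BP", "MF", "CC")

# Temporal-holdout boundaries.  2018-01-01 itself is uncovered by the three
# stated windows; it goes to train by default (configurable below).
TRAIN_BEFORE = _dt.date(2018, 1, 2)  # strictly earlier dates -> train
VAL_END = _dt.date(2020, 12, 31)  # inclusive


class EmptyLabelSpaceError(ValueError):
    """Raised when no GO term survives the count filters."""


@dataclass(frozen=True)
class ProteinIndex:
    """Ordered protein identifiers with a bijective id -> row mapping."""

    ids: tuple[str, ...]
    position: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("protein identifiers must be unique")
        object.__setattr__(self, "position", {p: i for i, p in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_file(cls, path) -> "ProteinIndex":
        with open(path) as fh:
            ids = tuple(line.strip() for line in fh if line.strip())
        return cls(ids)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.ids) + "\n")


@dataclass
class EvidenceNetwork:
    """A single evidence channel as a symmetric weighted adjacency matrix."""

    channel: str
    adjacency: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=np.float64)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if (a < 0).any():
            raise ValueError("adjacency entries must be non-negative")
        self.adjacency = a

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class AnnotationTable:
    """GO annotation records: protein, go_term, evidence, date, aspect."""

    records: pd.DataFrame

    REQUIRED = ("protein", "go_term", "evidence", "date", "aspect")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class AttributeMatrix:
    """Per-protein attribute indicators (Pfam domains, subcellular locations)."""

    x: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.ndim != 2 or self.x.shape[1] != len(self.columns):
            raise ValueError("attribute matrix shape does not match column names")

    @classmethod
    def from_tsv(cls, path, index: ProteinIndex) -> "AttributeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.reindex(list(index.ids)).fillna(0.0)
        return cls(df.to_numpy(dtype=np.float64), tuple(map(str, df.columns)))

    def to_tsv(self, path, index: ProteinIndex) -> None:
        pd.DataFrame(self.x, index=list(index.ids), columns=list(self.columns)).to_csv(
            path, sep="\t"
        )


@dataclass
class LabelMatrix:
    """Binary protein x GO-term labels with a train/val/test split.

    ``splits`` maps split name to row indices into the shared protein index;
    ``y[split]`` is the corresponding ``len(split) x K`` 0/1 matrix.
    """

    y: dict[str, np.ndarray]
    terms: tuple[str, ...]
    splits: dict[str, np.ndarray]

    def __post_init__(self):
        for name, mat in self.y.items():
            mat = np.asarray(mat)
            if not np.isin(mat, (0, 1)).all():
                raise ValueError("label entries must be 0/1")
            if mat.shape != (len(self.splits[name]), len(self.terms)):
                raise ValueError(f"shape mismatch in split {name!r}")
            self.y[name] = mat.astype(np.int8)
        idx = [np.asarray(v) for v in self.splits.values()]
        allv = np.concatenate(idx) if idx else np.array([], dtype=int)
        if len(np.unique(allv)) != len(allv):
            raise ValueError("splits must be pairwise disjoint")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def counts(self) -> pd.DataFrame:
        """Per-term positive counts per split (columns: split names + total)."""
        data = {name: self.y[name].sum(axis=0) for name in self.y}
        df = pd.DataFrame(data, index=list(self.terms))
        df["total"] = df.sum(axis=1)
        return df


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


def read_string_edges(path, channel: str, index: ProteinIndex) -> EvidenceNetwork:
    """Read one evidence channel from a STRING-style edge-list TSV.

    An interaction exists wherever the channel score is strictly positive.
    Duplicate pairs (including reversed order) keep the maximum score.  Scores
    are stored as given; normalization is a separate step.
    """
    df = _read_edge_table(path, channel)
    n = len(index)
    adj = np.zeros((n, n), dtype=np.float64)
    pos = index.position
    for row in df.itertuples(index=True):
        for pid in (row.protein1, row.protein2):
            if pid not in pos:
                raise ValueError(
                    f"unknown protein id {pid!r} in {path} (row {row.Index})"
                )
        try:
            score = float(row.score)
        except (TypeError, ValueError) as err:
            raise ValueError(
                f"malformed score {row.score!r} in {path} (row {row.Index})"
            ) from err
        if score <= 0:
            continue
        i, j = pos[row.protein1], pos[row.protein2]
        if score > adj[i, j]:
            adj[i, j] = adj[j, i] = score
    return EvidenceNetwork(channel=channel, adjacency=adj)


def _read_edge_table(path, channel: str) -> pd.DataFrame:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.readline()
    if not first.strip():
        return pd.DataFrame(columns=["protein1", "protein2", "score"])
    has_header = False
    if first:
        last_field = first.rstrip("\n").split("\t")[-1]
        try:
            float(last_field)
        except ValueError:
            has_header = True
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None, dtype=str)
    if df.empty:
        return pd.DataFrame(columns=["protein1", "protein2", "score"])
    if has_header and "channel" in df.columns:
        df = df[df["channel"] == channel]
        df = df.rename(columns={df.columns[0]: "protein1", df.columns[1]: "protein2"})
        if "score" not in df.columns:
            raise ValueError(f"combined edge file {path} lacks a 'score' column")
    else:
        if df.shape[1] < 3:
            raise ValueError(f"edge file {path} needs >=3 columns")
        df = df.iloc[:, :3]
        df.columns = ["protein1", "protein2", "score"]
    return df[["protein1", "protein2", "score"]]


def write_string_edges(net: EvidenceNetwork, index: ProteinIndex, path) -> None:
    """Write the upper triangle of a network as a headered edge-list TSV."""
    rows = []
    i_idx, j_idx = np.nonzero(np.triu(net.adjacency, k=1))
    for i, j in zip(i_idx, j_idx):
        rows.append((index.ids[i], index.ids[j], net.adjacency[i, j]))
    pd.DataFrame(rows, columns=["protein1", "protein2", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# temporal split and labels
# ---------------------------------------------------------------------------


def temporal_split(
    table: AnnotationTable,
    aspect: str | None = None,
    boundary_to_train: bool = True,
) -> pd.Series:
    """Assign each annotated protein to train/val/test by its earliest date.

    Dates strictly before 2018-01-01 give train, 2018-01-02 .. 2020-12-31
    validation, and 2021-01-01 onwards test.  The boundary day 2018-01-01 is
    uncovered by those windows and goes to train unless
    ``boundary_to_train=False`` (then validation).  Records with unparseable
    dates are dropped with a warning counting them.
    """
    df = table.records
    if aspect is not None:
        df = df[df["aspect"] == aspect]
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    bad = int(dates.isna().sum())
    if bad:
        warnings.warn(f"dropped {bad} annotation record(s) with unparseable dates")
    df = df.assign(_date=dates).dropna(subset=["_date"])
    earliest = df.groupby("protein")["_date"].min()

    boundary = pd.Timestamp(2018, 1, 1)

    def assign(d: pd.Timestamp) -> str:
        if d < boundary:
            return "train"
        if d == boundary:
            return "train" if boundary_to_train else "val"
        if d <= pd.Timestamp(VAL_END):
            return "val"
        return "test"

    return earliest.map(assign)


def onehot_labels(
    table: AnnotationTable,
    index: ProteinIndex,
    aspect: str,
    evidence_whitelist=EXPERIMENTAL_EVIDENCE_CODES,
    split_assignment: pd.Series | None = None,
) -> LabelMatrix:
    """One-hot encode whitelisted-evidence annotations of one GO aspect.

    ``y[i, k] = 1`` iff protein i carries a whitelisted-evidence annotation of
    term k (duplicates are idempotent).  When ``split_assignment`` is omitted
    the whole index forms a single ``"all"`` split.
    """
    if not evidence_whitelist:
        raise ValueError("evidence whitelist must be non-empty")
    if aspect not in ASPECTS:
        raise ValueError(f"aspect must be one of {ASPECTS}")
    df = table.records
    df = df[(df["aspect"] == aspect) & df["evidence"].isin(set(evidence_whitelist))]
    df = df[df["protein"].isin(index.position)]
    terms = tuple(sorted(df["go_term"].unique()))
    tpos = {t: k for k, t in enumerate(terms)}
    full = np.zeros((len(index), len(terms)), dtype=np.int8)
    for prot, term in zip(df["protein"], df["go_term"]):
        full[index.position[prot], tpos[term]] = 1

    if split_assignment is None:
        splits = {"all": np.arange(len(index))}
    else:
        splits = {}
        for name in ("train", "val", "test"):
            members = [
                index.position[p]
                for p in split_assignment.index[split_assignment == name]
                if p in index.position
            ]
            splits[name] = np.array(sorted(members), dtype=int)
    y = {name: full[rows] for name, rows in splits.items()}
    return LabelMatrix(y=y, terms=terms, splits=splits)


def filter_labels(
    labels: LabelMatrix,
    n_network: int,
    min_counts: dict[str, int] | None = None,
    max_frac: float = 0.05,
) -> LabelMatrix:
    """Drop GO terms failing the per-split support or generality filters.

    Retained terms have at least 10/5/1 positive proteins in train/val/test
    (when those splits exist) and no more than ``max_frac * n_network``
    positives in total.  Column order is preserved; the operation is
    idempotent.
    """
    if min_counts is None:
        min_counts = {"train": 10, "val": 5, "test": 1}
    keep = np.ones(labels.n_terms, dtype=bool)
    total = np.zeros(labels.n_terms, dtype=np.int64)
    for name, mat in labels.y.items():
        counts = mat.sum(axis=0)
        total += counts
        if name in min_counts:
            keep &= counts >= min_counts[name]
    keep &= total <= max_frac * n_network
    if not keep.any():
        raise EmptyLabelSpaceError(
            "no GO term survives the count filters; relax thresholds or add data"
        )
    terms = tuple(t for t, k in zip(labels.terms, keep) if k)
    y = {name: mat[:, keep] for name, mat in labels.y.items()}
    return LabelMatrix(y=y, terms=terms, splits=dict(labels.splits))


def filter_attributes(attrs: AttributeMatrix, min_support: int = 6) -> AttributeMatrix:
    """Drop attribute columns supported by fewer than ``min_support`` proteins."""
    support = (attrs.x != 0).sum(axis=0)
    keep = support >= min_support
    if not keep.any():
        warnings.warn("no attribute column survives the support filter")
    cols = tuple(c for c, k in zip(attrs.columns, keep) if k)
    return AttributeMatrix(x=attrs.x[:, keep], columns=cols)


def build_label_matrix(
    table: AnnotationTable,
    index: ProteinIndex,
    aspect: str,
    n_network: int | None = None,
    evidence_whitelist=EXPERIMENTAL_EVIDENCE_CODES,
    max_frac: float = 0.05,
) -> LabelMatrix:
    """Temporal split + one-hot encoding + count filters in one call."""
    assignment = temporal_split(table, aspect=aspect)
    labels = onehot_labels(
        table, index, aspect, evidence_whitelist, split_assignment=assignment
    )
    return filter_labels(labels, n_network or len(index), max_frac=max_frac)
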