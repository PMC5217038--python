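"""Tabular and graph I/O: the on-disk contracts every other stage consumes.

All matrices are delimited text (comma for ``.csv``, tab otherwise), first
column = feature id, header row = sample ids.  Missing values are written as
the single token ``NA``.  Gene identifiers are matched case-sensitively after
stripping surrounding whitespace.  Every reader/writer pair is a lossless
round trip (ids exact, values to better than 1e-12 via 17-digit floats).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stemomics")

NA_TOKEN = "NA"

__all__ = [
    "MatrixKind",
    "FeatureMatrix",
    "SampleSheet",
    "GeneSet",
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "write_network",
    "read_edge_table",
]


class MatrixKind(str, enum.Enum):
    """What the numbers in a :class:`FeatureMatrix` mean."""

    metabolite_conc = "metabolite_conc"
    expression_intensity = "expression_intensity"
    expression_log2 = "expression_log2"


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class FeatureMatrix:
    """A features x samples real matrix with explicit missing values (NaN).

    Parameters
    ----------
    features, samples
        Row and column identifiers; both must be unique.
    values
        2-D float array, shape ``(len(features), len(samples))``.  Missing
        entries are NaN, never silent zeros.
    kind
        Semantic tag; ``metabolite_conc`` values must be non-negative.
    """

    features: list[str]
    samples: list[str]
    values: np.ndarray
    kind: MatrixKind

    def __post_init__(self) -> None:
        self.features = [str(f).strip() for f in self.features]
        self.samples = [str(s).strip() for s in self.samples]
        self.kind = MatrixKind(self.kind)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.features),
            len(self.samples),
        ):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if self.values.size == 0:
            raise ValueError("empty matrix")
        dup = _first_duplicate(self.features)
        if dup is not None:
            raise ValueError(f"duplicate feature id: {dup!r}")
        dup = _first_duplicate(self.samples)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.kind is MatrixKind.metabolite_conc:
            with np.errstate(invalid="ignore"):
                if np.any(self.values < 0):
                    i, j = np.argwhere(self.values < 0)[0]
                    raise ValueError(
                        "negative concentration at "
                        f"({self.features[i]}, {self.samples[j]})"
                    )

    # -- conversion helpers -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: MatrixKind | str) -> "FeatureMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), kind)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return FeatureMatrix(
            list(self.features), list(sample_ids), self.values[:, idx], self.kind
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.features.index(f) for f in feature_ids]
        return FeatureMatrix(
            list(feature_ids), list(self.samples), self.values[idx, :], self.kind
        )


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class SampleSheet:
    """Per-sample metadata: condition (P/S), glucose (+/-), protein mass (mg)."""

    sample_id: list[str]
    condition: list[str]
    glucose: list[str]
    protein_mg: list[float]

    def __post_init__(self) -> None:
        n = len(self.sample_id)
        if not (len(self.condition) == len(self.glucose) == len(self.protein_mg) == n):
            raise ValueError("sample sheet columns have inconsistent lengths")
        dup = _first_duplicate(self.sample_id)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        for c in self.condition:
            if c not in ("P", "S"):
                raise ValueError(f"condition must be 'P' or 'S', got {c!r}")
        for g in self.glucose:
            if g not in ("plus", "minus"):
                raise ValueError(f"glucose must be 'plus' or 'minus', got {g!r}")
        for sid, p in zip(self.sample_id, self.protein_mg):
            if not (p > 0):
                raise ValueError(f"protein_mg must be > 0 for sample {sid!r}")

    def __len__(self) -> int:
        return len(self.sample_id)

    @property
    def group_key(self) -> list[str]:
        return [f"{c}:{g}" for c, g in zip(self.condition, self.glucose)]

    def samples_in(self, condition: str) -> list[str]:
        return [s for s, c in zip(self.sample_id, self.condition) if c == condition]

    def protein_for(self, sample: str) -> float:
        try:
            return self.protein_mg[self.sample_id.index(sample)]
        except ValueError:
            raise KeyError(f"sample {sample!r} not in sample sheet") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "condition": self.condition,
                "glucose": self.glucose,
                "protein_mg": self.protein_mg,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSheet":
        required = {"sample_id", "condition", "glucose", "protein_mg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        return cls(
            [str(s).strip() for s in df["sample_id"]],
            [str(c).strip() for c in df["condition"]],
            [str(g).strip() for g in df["glucose"]],
            [float(p) for p in df["protein_mg"]],
        )


@dataclass
class GeneSet:
    """A named gene list in the GMT sense (name, description, members)."""

    name: str
    description: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members = [str(m).strip() for m in self.members]
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        dup = _first_duplicate(self.members)
        if dup is not None:
            raise ValueError(f"gene set {self.name!r} has duplicate member {dup!r}")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path, kind: MatrixKind | str, delimiter: str | None = None
) -> FeatureMatrix:
    """Read a delimited feature x sample matrix.

    First column holds feature ids, the header row sample ids; ``NA`` encodes
    missing.  Row/column order is preserved exactly as on disk.  Duplicate
    feature ids and non-numeric cells are hard errors naming the offender.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty matrix in {path}")
    features = [str(f).strip() for f in df.index]
    dup = _first_duplicate(features)
    if dup is not None:
        raise ValueError(f"duplicate feature id in {path}: {dup!r}")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if cell == NA_TOKEN or cell == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {features[i]!r}, "
                    f"column {df.columns[j]!r} in {path}"
                ) from None
    return FeatureMatrix(features, [str(c) for c in df.columns], values, kind)


def write_matrix(
    mat: FeatureMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a :class:`FeatureMatrix`; inverse of :func:`read_matrix`."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = mat.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep=sep, na_rep=NA_TOKEN, float_format="%.17g")


def read_sample_sheet(path: str | Path, delimiter: str | None = None) -> SampleSheet:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    return SampleSheet.from_frame(pd.read_csv(path, sep=sep))


def write_sample_sheet(
    sheet: SampleSheet, path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    sheet.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name <tab> description <tab> member ids...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            members = [m.strip() for m in fields[2:] if m.strip()]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {fields[0]!r} is empty")
            sets.append(GeneSet(fields[0].strip(), fields[1].strip(), members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _edge_records(net) -> list[dict]:
    """Flatten a DiffNetwork into deterministic lexicographic edge rows."""
    genes = list(net.genes)
    rows = []
    for i, a in enumerate(genes):
        for j in range(i + 1, len(genes)):
            b = genes[j]
            ga, gb = sorted((a, b))
            r_p = float(net.r_P.loc[a, b])
            r_s = float(net.r_S.loc[a, b])
            pair = frozenset((a, b))
            selected = pair in net.selected
            if not selected and np.isnan(r_p) and np.isnan(r_s):
                continue
            rows.append(
                {
                    "gene_a": ga,
                    "gene_b": gb,
                    "r_P": r_p,
                    "r_S": r_s,
                    "delta": r_s - r_p,
                    "selected": selected,
                }
            )
    rows.sort(key=lambda r: (r["gene_a"], r["gene_b"]))
    return rows


def write_network(net, path: str | Path, format: str = "tsv_edgelist") -> None:
    """Export a differential co-expression network.

    ``tsv_edgelist`` writes columns gene_a/gene_b/r_P/r_S/delta/selected in
    lexicographic pair order; ``graphml`` carries the same edge attributes.
    """
    path = Path(path)
    rows = _edge_records(net)
    if format == "tsv_edgelist":
        df = pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "r_P", "r_S", "delta", "selected"]
        )
        df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.17g")
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph(tau=float(net.tau), direction=str(net.direction))
        g.add_nodes_from(net.genes)
        for r in rows:
            g.add_edge(
                r["gene_a"],
                r["gene_b"],
                r_P=r["r_P"],
                r_S=r["r_S"],
                delta=r["delta"],
                selected=r["selected"],
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read back a ``tsv_edgelist`` written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[NA_TOKEN])
    if len(df) and df["selected"].dtype != bool:
        df["selected"] = df["selected"].astype(str).str.lower() == "true"
    else:
        df["selected"] = df.get("selected", pd.Series(dtype=bool)).astype(bool)
    return df
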