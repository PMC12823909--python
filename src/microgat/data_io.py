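"""Reading, writing and normalization of abundance, label and embedding tables.

File dialect
------------
All tables are tab-delimited text with header identifiers:

* abundance — samples in rows (first column = sample id), genera in columns
  (first row = genus ids), relative abundances normalized to a within-sample
  sum of 100;
* labels — two columns ``sample_id`` and ``label`` with values in {0, 1}
  (1 = disease, 0 = control);
* embeddings — genera in rows (first column = genus id), one fixed-dimension
  genomic vector per genus (768 dimensions for the genome-language-model
  vectors used on real data; any dimension is accepted).

One canonical dialect avoids silent transposition bugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("microgat")

__all__ = [
    "AbundanceTable",
    "EmbeddingTable",
    "load_dataset",
    "read_abundance",
    "read_labels",
    "read_embeddings",
    "write_abundance",
    "write_labels",
    "write_embeddings",
    "normalize_to_percent",
    "aggregate_species_to_genus",
]


def _check_unique(ids, what: str):
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class AbundanceTable:
    """Samples x genera relative-abundance matrix with optional binary labels."""

    sample_ids: list[str]
    genus_ids: list[str]
    values: np.ndarray  # (n_samples, n_genera), non-negative
    labels: dict[str, int] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.validate()

    def validate(self):
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.genus_ids, "genus")
        if self.values.shape != (len(self.sample_ids), len(self.genus_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.genus_ids)} genera"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundance values must be finite")
        if np.any(self.values < 0):
            raise ValueError("abundance values must be non-negative")
        if self.labels is not None:
            missing = [s for s in self.sample_ids if s not in self.labels]
            if missing:
                raise ValueError(f"labels missing for sample(s): {missing}")
            extra = set(self.labels) - set(self.sample_ids)
            if extra:
                raise ValueError(f"labels refer to unknown sample(s): {sorted(extra)}")
            bad = {s: v for s, v in self.labels.items() if v not in (0, 1)}
            if bad:
                raise ValueError(f"labels must be 0 or 1, got {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genera(self) -> int:
        return len(self.genus_ids)

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("table carries no labels")
        return np.array([self.labels[s] for s in self.sample_ids], dtype=np.int64)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.genus_ids)

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        labels = (
            {s: self.labels[s] for s in sample_ids} if self.labels is not None else None
        )
        return AbundanceTable(
            list(sample_ids), list(self.genus_ids), self.values[idx], labels
        )


@dataclass
class EmbeddingTable:
    """One fixed-dimension genomic vector per genus."""

    genus_ids: list[str]
    vectors: np.ndarray  # (n_genera, dim)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        _check_unique(self.genus_ids, "genus")
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.genus_ids):
            raise ValueError(
                f"embedding matrix shape {self.vectors.shape} does not match "
                f"{len(self.genus_ids)} genera"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding values must be finite")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, genus_id: str) -> np.ndarray:
        return self.vectors[self.genus_ids.index(genus_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.vectors,
            index=self.genus_ids,
            columns=[f"d{i}" for i in range(self.dim)],
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_matrix(path, what: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], f"{what} column")  # pandas mangles duplicates
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(list(df.index), f"{what} row")
    _check_unique(list(df.columns), f"{what} column")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {what} table at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}: {df.iloc[bad[0], bad[1]]!r}"
        )
    return numeric


def read_abundance(path) -> AbundanceTable:
    df = _read_matrix(path, "abundance")
    return AbundanceTable(
        [str(s) for s in df.index], [str(g) for g in df.columns], df.to_numpy()
    )


def read_labels(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels file needs sample_id and label columns")
    labels: dict[str, int] = {}
    for sample, value in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if sample in labels:
            raise ValueError(f"duplicate sample identifier in labels: {sample!r}")
        try:
            v = int(value)
        except (TypeError, ValueError):
            raise ValueError(f"label for sample {sample!r} is not an integer: {value!r}")
        if v not in (0, 1):
            raise ValueError(f"label for sample {sample!r} outside {{0,1}}: {v}")
        labels[str(sample)] = v
    return labels


def read_embeddings(path) -> EmbeddingTable:
    df = _read_matrix(path, "embedding")
    return EmbeddingTable([str(g) for g in df.index], df.to_numpy())


def load_dataset(
    abundance_path, labels_path, embeddings_path
) -> tuple[AbundanceTable, EmbeddingTable]:
    """Load and cross-validate the three input tables.

    Genera present in the abundance table but absent from the embedding table
    are dropped with a warning (genome-language-model coverage of rare taxa is
    incomplete on real data); samples and labels must align exactly.
    """
    table = read_abundance(abundance_path)
    labels = read_labels(labels_path)
    embeddings = read_embeddings(embeddings_path)

    missing_labels = [s for s in table.sample_ids if s not in labels]
    if missing_labels:
        raise ValueError(
            f"labels file is missing sample(s): {missing_labels}"
        )
    table = replace_labels(table, {s: labels[s] for s in table.sample_ids})

    emb_set = set(embeddings.genus_ids)
    missing = [g for g in table.genus_ids if g not in emb_set]
    if missing:
        logger.warning(
            "dropping %d genera without genomic embeddings: %s",
            len(missing),
            ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
        )
        keep = [i for i, g in enumerate(table.genus_ids) if g in emb_set]
        table = AbundanceTable(
            table.sample_ids,
            [table.genus_ids[i] for i in keep],
            table.values[:, keep],
            table.labels,
        )
    # restrict embeddings to (and order by) the abundance genera
    order = [embeddings.genus_ids.index(g) for g in table.genus_ids]
    embeddings = EmbeddingTable(list(table.genus_ids), embeddings.vectors[order])
    return table, embeddings


def replace_labels(table: AbundanceTable, labels: dict[str, int]) -> AbundanceTable:
    return AbundanceTable(table.sample_ids, table.genus_ids, table.values, labels)


_FLOAT_FMT = "%.12g"


def write_abundance(table: AbundanceTable, path):
    table.to_dataframe().to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_labels(labels: dict[str, int], path):
    df = pd.DataFrame(
        {"sample_id": list(labels.keys()), "label": list(labels.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def write_embeddings(embeddings: EmbeddingTable, path):
    embeddings.to_dataframe().to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# normalization & aggregation


def normalize_to_percent(table: AbundanceTable) -> AbundanceTable:
    """Rescale every sample so its abundances sum to 100.

    Zeros are preserved and within-sample proportions are unchanged; the
    operation is idempotent.
    """
    sums = table.values.sum(axis=1)
    zero_rows = np.flatnonzero(sums <= 0)
    if zero_rows.size:
        raise ValueError(
            f"sample {table.sample_ids[zero_rows[0]]!r} has zero total abundance"
        )
    values = table.values * (100.0 / sums)[:, None]
    return AbundanceTable(table.sample_ids, table.genus_ids, values, table.labels)


def aggregate_species_to_genus(
    species_abundance: AbundanceTable,
    species_to_genus: dict[str, str],
    species_embeddings: EmbeddingTable | None = None,
) -> tuple[AbundanceTable, EmbeddingTable | None]:
    """Collapse a species-level table to genus level.

    Genus abundance is the sum of its species' abundances per sample; the
    genus genomic vector is the arithmetic mean of its species' vectors.
    """
    unmapped = [s for s in species_abundance.genus_ids if s not in species_to_genus]
    if unmapped:
        raise ValueError(f"species with no genus mapping: {unmapped}")
    genera: list[str] = []
    members: dict[str, list[int]] = {}
    for i, sp in enumerate(species_abundance.genus_ids):
        g = species_to_genus[sp]
        if g not in members:
            members[g] = []
            genera.append(g)
        members[g].append(i)

    values = np.zeros((species_abundance.n_samples, len(genera)))
    for j, g in enumerate(genera):
        values[:, j] = species_abundance.values[:, members[g]].sum(axis=1)
    genus_table = AbundanceTable(
        species_abundance.sample_ids, genera, values, species_abundance.labels
    )

    genus_embeddings = None
    if species_embeddings is not None:
        pos = {s: i for i, s in enumerate(species_embeddings.genus_ids)}
        missing = [
            sp for sp in species_abundance.genus_ids if sp not in pos
        ]
        if missing:
            raise ValueError(f"species missing from embedding table: {missing}")
        vecs = np.zeros((len(genera), species_embeddings.dim))
        for j, g in enumerate(genera):
            rows = [pos[species_abundance.genus_ids[i]] for i in members[g]]
            vecs[j] = species_embeddings.vectors[rows].mean(axis=0)
        genus_embeddings = EmbeddingTable(list(genera), vecs)
    return genus_table, genus_embeddings
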