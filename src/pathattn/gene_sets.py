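"""Gene-set collections and the binary gene x set mask matrix.

The mask M (genes x gene sets, entries 0/1) gates the embedding layer: a
gene may feed a gene-set token only if it belongs to that set.  Masks come
from GMT files (MSigDB dialect) or, when no curated knowledge is available,
from random membership at a chosen connection density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class GmtParseError(ValueError):
    """Raised for malformed GMT lines or collections emptied by restriction."""


@dataclass(frozen=True)
class GeneVocabulary:
    """Ordered gene identifiers defining the model's input dimension."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("gene vocabulary must be non-empty")
        lowered = [g.lower() for g in self.names]
        if len(set(lowered)) != len(lowered):
            dupes = sorted({g for g in lowered if lowered.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers (case-insensitive): {dupes[:10]}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self) -> dict[str, int]:
        """Case-normalized name -> column position."""
        return {g.lower(): i for i, g in enumerate(self.names)}


@dataclass
class GeneSetCollection:
    """Named gene sets; the raw material for a mask matrix."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class MaskMatrix:
    """Binary genes x gene-sets membership matrix.

    ``values[i, j] == 1`` iff gene ``i`` belongs to set ``j``.  Rows follow
    ``gene_names``; all-zero rows are allowed (genes outside every retained
    set stay in the vocabulary but cannot influence any token).
    """

    values: np.ndarray
    gene_names: GeneVocabulary
    set_names: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n, k = self.values.shape
        if n != len(self.gene_names):
            raise ValueError("mask row count does not match vocabulary size")
        if k != len(self.set_names):
            raise ValueError("mask column count does not match set names")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")
        if (self.values.sum(axis=0) < 1).any():
            empty = [self.set_names[j] for j in np.where(self.values.sum(axis=0) < 1)[0]]
            raise ValueError(f"mask columns with no member genes: {empty[:10]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_sets(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write the mask as TSV (gene rows, set columns) plus a sidecar of parameters."""
        import pandas as pd

        path = Path(path)
        df = pd.DataFrame(
            self.values.astype(int), index=list(self.gene_names.names), columns=list(self.set_names)
        )
        df.to_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".params.txt")
        with open(sidecar, "w") as fh:
            for key, val in self.params.items():
                fh.write(f"{key}\t{val}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MaskMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(dtype=np.float64),
            gene_names=GeneVocabulary(tuple(str(g) for g in df.index)),
            set_names=tuple(str(c) for c in df.columns),
        )


def parse_gmt(path: str | Path, vocabulary: GeneVocabulary | None = None) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> gene ...) into a collection.

    When ``vocabulary`` is given, each set is restricted to genes present in
    it (matched case-insensitively); sets emptied by the restriction are
    dropped, and dropping every set is an error.  Tolerates CRLF line endings
    and trailing tabs.
    """
    path = Path(path)
    vocab_index = vocabulary.index() if vocabulary is not None else None
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected name, description and >=1 gene, "
                    f"got {len(fields)} field(s)"
                )
            name, _desc, *genes = fields
            if name in sets:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            # de-duplicate while preserving order
            seen: set[str] = set()
            members: list[str] = []
            for g in genes:
                key = g.lower()
                if key in seen:
                    continue
                seen.add(key)
                if vocab_index is None:
                    members.append(g)
                elif key in vocab_index:
                    # report the vocabulary's spelling so downstream lookups agree
                    members.append(vocabulary.names[vocab_index[key]])
            if members:
                sets[name] = members
    if not sets:
        raise GmtParseError(
            f"{path}: zero surviving sets"
            + (" after restriction to the vocabulary" if vocabulary is not None else "")
        )
    return GeneSetCollection(sets=sets, provenance=str(path))


def build_mask(
    collection: GeneSetCollection,
    vocabulary: GeneVocabulary,
    max_gs_size: int = 300,
    max_n_gs: int = 300,
    oversize: str = "drop",
) -> MaskMatrix:
    """Build the binary mask from a gene-set collection.

    Sets are restricted to the vocabulary; sets larger than ``max_gs_size``
    are dropped (or truncated to their first ``max_gs_size`` members with
    ``oversize="truncate"``); at most ``max_n_gs`` sets are kept, preferring
    the largest, ties broken by name.
    """
    if oversize not in ("drop", "truncate"):
        raise ValueError("oversize must be 'drop' or 'truncate'")
    vocab_index = vocabulary.index()
    restricted: dict[str, list[str]] = {}
    for name, genes in collection.sets.items():
        members = [g for g in genes if g.lower() in vocab_index]
        if not members:
            continue
        if len(members) > max_gs_size:
            if oversize == "drop":
                continue
            members = members[:max_gs_size]
        restricted[name] = members
    if not restricted:
        raise GmtParseError("zero gene sets survive vocabulary/size filtering")
    # keep the max_n_gs largest; ties broken lexicographically by name
    ranked = sorted(restricted.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:max_n_gs]
    kept = sorted(name for name, _ in ranked)  # stable, name-ordered columns
    values = np.zeros((len(vocabulary), len(kept)), dtype=np.float64)
    for j, name in enumerate(kept):
        for g in restricted[name]:
            values[vocab_index[g.lower()], j] = 1.0
    return MaskMatrix(
        values=values,
        gene_names=vocabulary,
        set_names=tuple(kept),
        params={
            "source": collection.provenance,
            "max_gs_size": max_gs_size,
            "max_n_gs": max_n_gs,
            "oversize": oversize,
        },
    )


def random_mask(
    vocabulary: GeneVocabulary, k: int, density: float, seed: int
) -> MaskMatrix:
    """Random mask: ``k`` columns, each with ``ceil(density * n)`` member genes.

    Emulates the no-expert-knowledge setting (e.g. 1% or 5% reserved
    connections): member genes are sampled uniformly without replacement,
    independently per column, reproducibly from ``seed``.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must be in (0, 1], got {density}")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(vocabulary)
    per_col = int(np.ceil(density * n))
    if per_col < 1:
        raise ValueError("density too small: no connections per column")
    rng = np.random.default_rng(seed)
    values = np.zeros((n, k), dtype=np.float64)
    for j in range(k):
        values[rng.choice(n, size=per_col, replace=False), j] = 1.0
    return MaskMatrix(
        values=values,
        gene_names=vocabulary,
        set_names=tuple(f"RANDOM_{j}" for j in range(k)),
        params={"source": "random", "k": k, "density": density, "seed": seed},
    )
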