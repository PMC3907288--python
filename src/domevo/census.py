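"""Fold-family census matrices and phylogenetic character coding.

The raw input is a genome census: for every proteome, the number of
protein domains assigned to each SCOP fold family (FF), identified by its
concise classification string (css, ``class.fold.superfamily.family``,
e.g. ``c.37.1.12``).  Two character codings are supported:

* **abundance** — counts are log-rescaled onto 24 ordered states written
  with the alphanumeric alphabet ``0-9`` + ``A-N``::

      state = round( ln(g + 1) / ln(g_max + 1) * 23 )

  where ``g`` is the count in one cell and ``g_max`` the maximum count in
  the whole matrix.  The ``+1`` offset pins zero abundance to state 0,
  which the 0-ancestral polarization of the trees of life requires.  The
  ratio is invariant to the logarithm base.

* **occurrence** — binary presence/absence (states ``0``/``1``).

Matrices are written to NEXUS (PAUP*-compatible DATA block) and relaxed
PHYLIP, and re-read losslessly.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ABUNDANCE_SYMBOLS",
    "OCCURRENCE_SYMBOLS",
    "SUPERKINGDOMS",
    "FFKey",
    "ProteomeRecord",
    "AbundanceMatrix",
    "CodedMatrix",
    "read_assignment_table",
    "build_abundance_matrix",
    "encode_abundance",
    "encode_occurrence",
    "transpose_for_tod",
    "write_character_matrix",
    "read_character_matrix",
]

logger = logging.getLogger(__name__)

ABUNDANCE_SYMBOLS = "0123456789ABCDEFGHIJKLMN"  # 24 ordered states
OCCURRENCE_SYMBOLS = "01"
SUPERKINGDOMS = ("A", "B", "E")  # Archaea, Bacteria, Eukarya

_CSS_RE = re.compile(r"^[a-g]\.\d+\.\d+\.\d+$")


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input parsed but violates a domain constraint."""


@dataclass(frozen=True)
class FFKey:
    """A SCOP fold family identified by its concise classification string."""

    css: str
    name: Optional[str] = None

    def __post_init__(self):
        if not _CSS_RE.match(self.css):
            raise ValidationError(f"invalid SCOP css string: {self.css!r}")


@dataclass(frozen=True)
class ProteomeRecord:
    id: str
    superkingdom: str
    name: Optional[str] = None

    def __post_init__(self):
        if self.superkingdom not in SUPERKINGDOMS:
            raise ValidationError(
                f"superkingdom of {self.id!r} must be one of "
                f"{SUPERKINGDOMS}, got {self.superkingdom!r}")


@dataclass
class AbundanceMatrix:
    """Proteomes x fold families count grid.

    ``counts`` is indexed by proteome id (rows, sorted) and css (columns,
    sorted); ``proteomes`` carries the superkingdom labels in row order.
    """

    counts: pd.DataFrame
    proteomes: pd.DataFrame  # columns: id, superkingdom, name; index = id
    ff_names: dict = field(default_factory=dict)  # css -> free-text name

    @property
    def g_max(self) -> int:
        return int(self.counts.to_numpy().max())

    @property
    def proteome_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def css_list(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def superkingdom_of(self, proteome_id: str) -> str:
        return self.proteomes.loc[proteome_id, "superkingdom"]

    def subset_proteomes(self, ids, drop_empty_ffs: bool = True) -> "AbundanceMatrix":
        ids = sorted(ids)
        missing = set(ids) - set(self.counts.index)
        if missing:
            raise ValidationError(f"unknown proteomes: {sorted(missing)}")
        counts = self.counts.loc[ids]
        if drop_empty_ffs:
            counts = counts.loc[:, counts.sum(axis=0) > 0]
        return AbundanceMatrix(counts=counts.copy(),
                               proteomes=self.proteomes.loc[ids].copy(),
                               ff_names=self.ff_names)


@dataclass
class CodedMatrix:
    """Ordered-state character matrix (values in ``0..k-1``).

    ``taxa`` are the tree tips (proteomes for a ToL, fold families for a
    ToD after :func:`transpose_for_tod`); ``characters`` the opposite
    axis.  ``meta`` optionally carries per-proteome metadata.
    """

    taxa: list[str]
    characters: list[str]
    states: np.ndarray  # (n_taxa, n_characters), int
    k: int
    symbols: str
    meta: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ValidationError("states grid does not match axis lengths")
        if len(self.symbols) != self.k:
            raise ValidationError("symbol alphabet length must equal k")
        if self.states.size and (self.states.min() < 0 or self.states.max() >= self.k):
            raise ValidationError("states must lie in 0..k-1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def symbol_row(self, i: int) -> str:
        return "".join(self.symbols[s] for s in self.states[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.taxa, columns=self.characters)

    def subset_characters(self, keep) -> "CodedMatrix":
        idx = [self.characters.index(c) for c in keep]
        return CodedMatrix(taxa=list(self.taxa), characters=list(keep),
                           states=self.states[:, idx], k=self.k,
                           symbols=self.symbols, meta=self.meta)

    def subset_taxa(self, keep) -> "CodedMatrix":
        keep = list(keep)
        idx = [self.taxa.index(t) for t in keep]
        meta = self.meta.loc[keep] if self.meta is not None else None
        return CodedMatrix(taxa=keep, characters=list(self.characters),
                           states=self.states[idx], k=self.k,
                           symbols=self.symbols, meta=meta)


# ----------------------------------------------------------------------
# reading the assignment table
# ----------------------------------------------------------------------
REQUIRED_COLUMNS = ("proteome_id", "superkingdom", "css", "count")


def read_assignment_table(path: Union[str, Path]) -> AbundanceMatrix:
    """Read a per-proteome FF assignment TSV into an abundance matrix.

    Expected header columns: ``proteome_id``, ``superkingdom``, ``css``,
    ``count`` (an optional ``name`` column supplies FF names).  Duplicate
    (proteome, css) rows are summed.  Fold families with only zero counts
    are dropped with a logged warning.  Axes are sorted for deterministic
    downstream output.
    """
    df = pd.read_csv(path, sep="\t", dtype={"proteome_id": str, "css": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"assignment table {path} is missing "
                              f"required column {col!r}")
    return build_abundance_matrix(df)


def build_abundance_matrix(df: pd.DataFrame) -> AbundanceMatrix:
    """Build an :class:`AbundanceMatrix` from a long-format assignment
    DataFrame (same columns as :func:`read_assignment_table`)."""
    bad_sk = set(df["superkingdom"]) - set(SUPERKINGDOMS)
    if bad_sk:
        raise ValidationError(f"unknown superkingdom codes: {sorted(bad_sk)}")
    counts_raw = pd.to_numeric(df["count"], errors="raise")
    if (counts_raw < 0).any():
        raise ValidationError("negative counts in assignment table")
    if not (counts_raw == counts_raw.astype(int)).all():
        raise ValidationError("non-integer counts in assignment table")
    for css in df["css"].unique():
        FFKey(css)  # validates syntax

    sk_per_prot = df.groupby("proteome_id")["superkingdom"].nunique()
    conflicted = sk_per_prot[sk_per_prot > 1]
    if len(conflicted):
        raise ValidationError(
            f"proteomes with conflicting superkingdom labels: "
            f"{sorted(conflicted.index)}")

    wide = (df.assign(count=counts_raw.astype(int))
              .pivot_table(index="proteome_id", columns="css",
                           values="count", aggfunc="sum", fill_value=0))
    wide = wide.sort_index(axis=0).sort_index(axis=1)

    empty = wide.columns[wide.sum(axis=0) == 0]
    if len(empty):
        logger.warning("dropping %d all-zero fold family column(s): %s",
                       len(empty), list(empty))
        wide = wide.drop(columns=empty)

    prot = (df[["proteome_id", "superkingdom"]].drop_duplicates()
            .set_index("proteome_id").sort_index())
    prot["name"] = None
    if "proteome_name" in df.columns:
        names = df.drop_duplicates("proteome_id").set_index("proteome_id")["proteome_name"]
        prot["name"] = names.reindex(prot.index)
    prot = prot.loc[wide.index]

    ff_names = {}
    if "name" in df.columns:
        ff_names = (df.dropna(subset=["name"]).drop_duplicates("css")
                    .set_index("css")["name"].to_dict())

    return AbundanceMatrix(counts=wide.astype(int), proteomes=prot,
                           ff_names=ff_names)


# ----------------------------------------------------------------------
# character coding
# ----------------------------------------------------------------------
def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (values here are non-negative).

    Centralized so the rounding convention can be swapped in one place;
    note ``np.round`` rounds half to even, which is *not* what we want.
    """
    return np.floor(x + 0.5).astype(np.int64)


def encode_abundance(m: AbundanceMatrix, k: int = 24) -> CodedMatrix:
    """Log-rescale counts onto ``k`` ordered states (default 24).

    ``state = round(ln(g+1) / ln(g_max+1) * (k-1))``; monotone
    non-decreasing in ``g`` for fixed ``g_max``.
    """
    g = m.counts.to_numpy(dtype=np.float64)
    g_max = m.g_max
    if g_max < 1:
        raise ValidationError("empty census: the matrix maximum count is 0")
    states = _round_half_up(np.log1p(g) / math.log1p(g_max) * (k - 1))
    symbols = ABUNDANCE_SYMBOLS[:k] if k <= len(ABUNDANCE_SYMBOLS) else None
    if symbols is None:
        raise ValidationError(f"no alphabet defined for k={k}")
    return CodedMatrix(taxa=m.proteome_ids, characters=m.css_list,
                       states=states, k=k, symbols=symbols,
                       meta=m.proteomes.copy())


def encode_occurrence(m: AbundanceMatrix) -> CodedMatrix:
    """Binary presence/absence coding (state 1 iff count > 0)."""
    states = (m.counts.to_numpy() > 0).astype(np.int64)
    return CodedMatrix(taxa=m.proteome_ids, characters=m.css_list,
                       states=states, k=2, symbols=OCCURRENCE_SYMBOLS,
                       meta=m.proteomes.copy())


def transpose_for_tod(m: CodedMatrix) -> CodedMatrix:
    """Swap axes so fold families become the taxa (tree-of-domains
    orientation); an involution."""
    return CodedMatrix(taxa=list(m.characters), characters=list(m.taxa),
                       states=m.states.T.copy(), k=m.k, symbols=m.symbols,
                       meta=None)


# ----------------------------------------------------------------------
# on-disk character matrices
# ----------------------------------------------------------------------
_SANITIZE_RE = re.compile(r"[^0-9A-Za-z_.\-]")


def _sanitize_labels(labels: list[str]) -> list[str]:
    out = [_SANITIZE_RE.sub("_", l) for l in labels]
    seen: dict[str, list[str]] = {}
    for orig, s in zip(labels, out):
        seen.setdefault(s, []).append(orig)
    collisions = {s: origs for s, origs in seen.items() if len(origs) > 1}
    if collisions:
        raise ValidationError(
            f"taxon labels collide after sanitization: {collisions}")
    return out


def write_character_matrix(m: CodedMatrix, fmt: str, path: Union[str, Path]) -> None:
    """Write a coded matrix as NEXUS (``fmt='nexus'``), relaxed PHYLIP
    (``'phylip'``) or a TSV dump (``'tsv'``).

    The NEXUS DATA block declares NTAX/NCHAR and the exact state alphabet
    in SYMBOLS, matching what PAUP* expects for standard multistate data.
    """
    path = Path(path)
    labels = _sanitize_labels(list(m.taxa))
    rows = [m.symbol_row(i) for i in range(m.n_taxa)]
    if fmt == "nexus":
        pad = max(len(l) for l in labels) + 2
        lines = ["#NEXUS", "", "BEGIN DATA;",
                 f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};",
                 f'    FORMAT DATATYPE=STANDARD SYMBOLS="{m.symbols}" MISSING=?;',
                 "    MATRIX"]
        for label, row in zip(labels, rows):
            lines.append(f"        {label.ljust(pad)}{row}")
        lines += ["    ;", "END;", ""]
        path.write_text("\n".join(lines))
    elif fmt == "phylip":
        pad = max(len(l) for l in labels) + 2
        lines = [f"{m.n_taxa} {m.n_characters}"]
        for label, row in zip(labels, rows):
            lines.append(f"{label.ljust(pad)}{row}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "tsv":
        m.to_frame().rename_axis("taxon").to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown character matrix format: {fmt!r}")


def read_character_matrix(path: Union[str, Path], fmt: str,
                          symbols: Optional[str] = None) -> CodedMatrix:
    """Read back a matrix written by :func:`write_character_matrix`.

    ``symbols`` may override alphabet detection (required for PHYLIP,
    where the alphabet is not declared in the file).  The missing-data
    symbol ``?`` is accepted on read and treated as state 0 (absence);
    it is never emitted.
    """
    path = Path(path)
    if fmt == "nexus":
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        text = path.read_text()
        msym = re.search(r'SYMBOLS\s*=\s*"([^"]+)"', text, flags=re.I)
        alphabet = symbols or (msym.group(1).replace(" ", "") if msym else None)
        if alphabet is None:
            raise FormatError(f"{path}: NEXUS file declares no SYMBOLS")
        taxa, rows = [], []
        for taxon in dm:
            taxa.append(taxon.label)
            rows.append("".join(str(c) for c in dm[taxon]))
    elif fmt == "phylip":
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        header = lines[0].split()
        ntax, nchar = int(header[0]), int(header[1])
        taxa, rows = [], []
        for line in lines[1:1 + ntax]:
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows.append(seq.strip())
        if any(len(r) != nchar for r in rows):
            raise FormatError(f"{path}: row lengths disagree with NCHAR")
        if symbols is None:
            raise FormatError("reading PHYLIP requires the symbols alphabet")
        alphabet = symbols
    else:
        raise ValueError(f"unknown character matrix format: {fmt!r}")

    lookup = {c: i for i, c in enumerate(alphabet)}
    lookup["?"] = 0  # missing treated as absence
    try:
        states = np.array([[lookup[c] for c in row] for row in rows], dtype=np.int64)
    except KeyError as e:  # pragma: no cover - malformed file
        raise FormatError(f"{path}: symbol {e} not in alphabet {alphabet!r}")
    characters = [f"char{i+1}" for i in range(states.shape[1])]
    return CodedMatrix(taxa=taxa, characters=characters, states=states,
                       k=len(alphabet), symbols=alphabet)
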