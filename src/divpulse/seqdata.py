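"""Aligned sequence data: reading, validation, masking, concatenation, site statistics.

Alignments are held as integer code matrices (one row per taxon, one column
per site).  Codes 0-3 are the unambiguous bases A, C, G, T; everything else
(IUPAC ambiguity codes and the gap character) is treated as missing for the
purposes of distance estimation and site statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, JoinError, MaskError

if TYPE_CHECKING:  # pragma: no cover - import for type hints only
    from .distmodels import ModelSpec

# Alphabet: unambiguous bases first so that ``code < 4`` tests for them.
ALPHABET = "ACGTRYSWKMBDHVN-"
_CODE_OF = {c: i for i, c in enumerate(ALPHABET)}
_CODE_OF["U"] = _CODE_OF["T"]
GAP_CODE = _CODE_OF["-"]
N_BASES = 4

#: purine (A, G) vs pyrimidine (C, T) class of the four unambiguous codes
BASE_CLASS = np.array([0, 1, 0, 1], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into integer codes (upper-cased, U -> T)."""
    s = seq.strip().upper()
    try:
        return np.array([_CODE_OF[c] for c in s], dtype=np.uint8)
    except KeyError as exc:
        raise AlignmentError(f"illegal character {exc.args[0]!r} in sequence") from None


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass
class AlignedSeqSet:
    """A fixed-length multiple sequence alignment with per-column partition labels."""

    taxon_ids: list[str]
    codes: np.ndarray  # (n_taxa, n_sites) uint8
    partition_of: np.ndarray  # (n_sites,) object array of partition names

    def __post_init__(self) -> None:
        self.taxon_ids = [t.strip() for t in self.taxon_ids]
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[1] < 1:
            raise AlignmentError("alignment must have >= 1 column")
        if len(self.taxon_ids) != self.codes.shape[0]:
            raise AlignmentError("taxon_ids and sequence rows differ in number")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dupes = sorted({t for t in self.taxon_ids if self.taxon_ids.count(t) > 1})
            raise AlignmentError(f"duplicate taxon ids: {dupes}")
        if any(not t for t in self.taxon_ids):
            raise AlignmentError("empty taxon id")
        self.partition_of = np.asarray(self.partition_of, dtype=object)
        if self.partition_of.shape != (self.codes.shape[1],):
            raise AlignmentError("partition_of must label every column exactly once")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, taxon: str) -> str:
        return decode(self.codes[self.taxon_ids.index(taxon)])

    def select_taxa(self, taxa: Sequence[str]) -> "AlignedSeqSet":
        """Row subset in the given order."""
        idx = [self.taxon_ids.index(t) for t in taxa]
        return AlignedSeqSet(list(taxa), self.codes[idx], self.partition_of.copy())

    def rename_taxa(self, alias: dict[str, str]) -> "AlignedSeqSet":
        """Apply an id alias table (e.g. specimen id -> species label)."""
        new_ids = [alias.get(t, t) for t in self.taxon_ids]
        return AlignedSeqSet(new_ids, self.codes.copy(), self.partition_of.copy())

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, row in zip(self.taxon_ids, self.codes):
                fh.write(f">{t}\n{decode(row)}\n")


@dataclass
class Partition:
    """One partition of a scheme: a named, ordered set of 0-based columns."""

    name: str
    columns: np.ndarray  # 0-based column indices, ordered
    model: "ModelSpec | None" = None
    rate: float | None = None  # subst/site/Ma, used by the sequence simulator
    codon_rate_mult: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.intp)


@dataclass
class PartitionScheme:
    partitions: list[Partition]
    codon_expansion: bool = False

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p in self.partitions:
            cols = set(p.columns.tolist())
            if cols & seen:
                raise AlignmentError(f"partition {p.name!r} overlaps another partition")
            seen |= cols

    def validate_against(self, aln: AlignedSeqSet) -> None:
        all_cols = np.sort(np.concatenate([p.columns for p in self.partitions]))
        if all_cols.size != aln.n_sites or not np.array_equal(
            all_cols, np.arange(aln.n_sites)
        ):
            raise AlignmentError("partitions must jointly cover all columns exactly once")

    def expand_codon_positions(self) -> "PartitionScheme":
        """Split each coding partition into codon positions 1/2/3 (by column order)."""
        out: list[Partition] = []
        for p in self.partitions:
            if p.codon_rate_mult is None and not self.codon_expansion:
                out.append(p)
                continue
            for pos in range(3):
                out.append(
                    Partition(
                        f"{p.name}_pos{pos + 1}",
                        p.columns[pos::3],
                        model=p.model,
                        rate=p.rate,
                    )
                )
        return PartitionScheme(out)

    @classmethod
    def single(cls, aln: AlignedSeqSet, model: "ModelSpec | None" = None, name: str = "all"):
        return cls([Partition(name, np.arange(aln.n_sites), model=model)])


@dataclass
class SiteStats:
    n_sites: int
    n_variable: int
    n_parsimony_informative: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_parsimony_informative <= self.n_variable <= self.n_sites:
            raise ValueError("inconsistent site statistics")


def read_fasta_alignment(path, partition_name: str = "all") -> AlignedSeqSet:
    """Read an aligned FASTA file into a validated :class:`AlignedSeqSet`.

    Sequences are upper-cased and RNA ``U`` is mapped to ``T``.  All records
    must have identical length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = [r.id.strip() for r in records]
    rows = [encode(str(r.seq)) for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(
            f"unequal sequence lengths in {path}: {sorted(lengths)}"
        )
    codes = np.vstack(rows)
    partition_of = np.full(codes.shape[1], partition_name, dtype=object)
    return AlignedSeqSet(ids, codes, partition_of)


def read_mask_file(path) -> list[int]:
    """Read a 1-based column mask: one index per line, '#' starts a comment."""
    mask: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            for tok in re.split(r"[,\s]+", line):
                if tok:
                    mask.append(int(tok))
    return mask


def apply_column_mask(
    aln: AlignedSeqSet, mask: Iterable[int]
) -> tuple[AlignedSeqSet, float]:
    """Remove the 1-based ``mask`` columns; return the reduced alignment and
    the fraction of columns removed."""
    mask_idx = sorted(set(int(m) for m in mask))
    if not mask_idx:
        return (
            AlignedSeqSet(list(aln.taxon_ids), aln.codes.copy(), aln.partition_of.copy()),
            0.0,
        )
    if mask_idx[0] < 1 or mask_idx[-1] > aln.n_sites:
        bad = [m for m in mask_idx if not 1 <= m <= aln.n_sites]
        raise MaskError(f"mask indices out of range 1..{aln.n_sites}: {bad}")
    keep = np.ones(aln.n_sites, dtype=bool)
    keep[np.array(mask_idx) - 1] = False
    if not keep.any():
        raise MaskError("mask removes every column")
    fraction = len(mask_idx) / aln.n_sites
    return (
        AlignedSeqSet(list(aln.taxon_ids), aln.codes[:, keep], aln.partition_of[keep]),
        fraction,
    )


def concatenate(
    alns: Sequence[AlignedSeqSet], names: Sequence[str] | None = None
) -> tuple[AlignedSeqSet, PartitionScheme]:
    """Concatenate gene alignments on the intersection of their taxon sets.

    Columns are appended in input order and a per-gene partition scheme is
    returned.  Taxa present in only some genes are dropped.
    """
    if len(alns) < 2:
        raise JoinError("need at least 2 alignments to concatenate")
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(alns))]
    common = [t for t in alns[0].taxon_ids if all(t in a.taxon_ids for a in alns[1:])]
    if not common:
        raise JoinError("no taxa shared by all alignments")
    blocks = [a.select_taxa(common) for a in alns]
    codes = np.hstack([b.codes for b in blocks])
    partition_of = np.concatenate(
        [np.full(b.n_sites, nm, dtype=object) for b, nm in zip(blocks, names)]
    )
    offsets = np.cumsum([0] + [b.n_sites for b in blocks])
    parts = [
        Partition(nm, np.arange(offsets[i], offsets[i + 1]))
        for i, nm in enumerate(names)
    ]
    return AlignedSeqSet(common, codes, partition_of), PartitionScheme(parts)


def site_stats(aln: AlignedSeqSet) -> SiteStats:
    """Count variable and parsimony-informative columns.

    A column is variable when it shows >= 2 distinct unambiguous bases, and
    parsimony-informative when >= 2 unambiguous bases each occur in >= 2
    taxa.  Gaps and ambiguity codes never contribute.
    """
    counts = np.zeros((N_BASES, aln.n_sites), dtype=np.int64)
    for b in range(N_BASES):
        counts[b] = (aln.codes == b).sum(axis=0)
    present = (counts > 0).sum(axis=0)
    n_variable = int((present >= 2).sum())
    n_pi = int(((counts >= 2).sum(axis=0) >= 2).sum())
    return SiteStats(aln.n_sites, n_variable, n_pi)


def site_stats_report(aln: AlignedSeqSet, scheme: PartitionScheme | None = None):
    """Per-partition site statistics as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    if scheme is not None:
        for p in scheme.partitions:
            sub = AlignedSeqSet(
                list(aln.taxon_ids), aln.codes[:, p.columns], aln.partition_of[p.columns]
            )
            st = site_stats(sub)
            rows.append((p.name, st.n_sites, st.n_variable, st.n_parsimony_informative))
    st = site_stats(aln)
    rows.append(("total", st.n_sites, st.n_variable, st.n_parsimony_informative))
    return pd.DataFrame(
        rows, columns=["partition", "n_sites", "n_variable", "n_parsimony_informative"]
    )
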