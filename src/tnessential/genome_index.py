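"""Reference-genome indexing for mariner Tn-seq.

The mariner/Himar1 transposon inserts exclusively at TA dinucleotides.  Each
insertion is observed through the ~16 nt of genomic sequence flanking the TA
on either side, so a read can only be assigned to a site if that flank is
unique genome-wide.  This module enumerates TA sites, extracts both flanks
per site, flags flank uniqueness (the operational form of repeat filtering),
and assigns informative (unique) flanks to genes after a strand-aware 3'
trim.

Coordinate conventions: GFF3 coordinates are 1-based inclusive externally;
everything internal is 0-based half-open.  A TA site is identified by the
0-based position of its T on the forward strand (TA is its own reverse
complement, so one strand scan suffices).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

_IUPAC = "ACGTRYSWKMBDHVN"
_BAD_CHAR = re.compile(f"[^{_IUPAC}]")
_TA = re.compile(r"(?=TA)")
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def enumerate_ta_sites(sequence: str) -> np.ndarray:
    """All 0-based positions p with sequence[p:p+2] == "TA".

    Overlapping occurrences count ("TATA" -> [0, 2]).  Raises ValueError on
    the first non-IUPAC character, naming the symbol and its position.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = _BAD_CHAR.search(seq)
    if bad:
        raise ValueError(
            f"non-DNA character {seq[bad.start()]!r} at position {bad.start()}"
        )
    return np.fromiter((m.start() for m in _TA.finditer(seq)), dtype=np.int64)


@dataclass
class ReferenceGenome:
    """A single replicon plus its enumerated TA sites."""

    id: str
    sequence: str
    ta_positions: np.ndarray

    @classmethod
    def build(cls, seq_id: str, sequence: str) -> "ReferenceGenome":
        sequence = sequence.upper()
        return cls(seq_id, sequence, enumerate_ta_sites(sequence))

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        rec = records[0]  # single-replicon analysis
        return cls.build(rec.id, str(rec.seq))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_ta_sites(self) -> int:
        return len(self.ta_positions)


@dataclass
class FlankIndex:
    """Both k-nt flanks of every TA site, with genome-wide uniqueness flags.

    The left flank is the k nt immediately 5' of the TA, reverse-complemented
    (the orientation in which it is sequenced); the right flank is the k nt
    immediately 3' of the TA on the forward strand.  A flank is unique iff
    its sequence occurs exactly once in the pool of all flanks over both
    sides and all sites.  Flanks are stored in TA-site order, so
    ``site_pos`` is non-decreasing.
    """

    k: int
    site_pos: np.ndarray       # per flank: 0-based T position of its TA site
    side: np.ndarray           # per flank: "L" or "R"
    flank_seq: np.ndarray      # per flank: k-mer string
    unique: np.ndarray         # per flank: bool
    n_sites: int
    _prefix_maps: dict = field(default_factory=dict, repr=False)

    @property
    def n_flanks(self) -> int:
        return len(self.site_pos)

    @property
    def n_unique(self) -> int:
        """Genome-wide count of unique flanks (the U of the hit-probability f)."""
        return int(self.unique.sum())

    def prefix_map(self, min_match: int) -> dict:
        """Map flank prefixes of length min_match to a flank index.

        Prefixes belonging to a non-unique flank, or shared by more than one
        flank, map to -1 (repeat/ambiguous).  Cached per min_match.
        """
        if min_match > self.k:
            raise ValueError(f"min_match={min_match} exceeds flank length k={self.k}")
        if min_match not in self._prefix_maps:
            pm: dict = {}
            for i, (seq, uniq) in enumerate(zip(self.flank_seq, self.unique)):
                pre = seq[:min_match]
                if not uniq:
                    pm[pre] = -1
                elif pre in pm:
                    if pm[pre] != i:
                        pm[pre] = -1
                else:
                    pm[pre] = i
            self._prefix_maps[min_match] = pm
        return self._prefix_maps[min_match]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_pos": self.site_pos,
                "side": self.side,
                "flank_seq": self.flank_seq,
                "unique": self.unique.astype(int),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_flank_index(genome: ReferenceGenome, k: int = 16) -> FlankIndex:
    """Extract both flanks per TA site and flag genome-wide uniqueness.

    Sites too close to a sequence end contribute fewer than two flanks.
    """
    if k < 8:
        raise ValueError(f"flank length k={k} < 8")
    seq = genome.sequence
    n = len(seq)
    pos_list, side_list, seqs = [], [], []
    for p in genome.ta_positions:
        p = int(p)
        if p >= k:
            pos_list.append(p)
            side_list.append("L")
            seqs.append(revcomp(seq[p - k : p]))
        if p + 2 + k <= n:
            pos_list.append(p)
            side_list.append("R")
            seqs.append(seq[p + 2 : p + 2 + k])
    multiplicity = Counter(seqs)
    unique = np.fromiter((multiplicity[s] == 1 for s in seqs), dtype=bool, count=len(seqs))
    return FlankIndex(
        k=k,
        site_pos=np.asarray(pos_list, dtype=np.int64),
        side=np.asarray(side_list, dtype="<U1"),
        flank_seq=np.asarray(seqs, dtype=object),
        unique=unique,
        n_sites=genome.n_ta_sites,
    )


@dataclass
class GeneModel:
    """One annotated gene with its informative (unique) TA flanks.

    ``u_g`` is the number of unique flanks whose TA site lies inside the
    3'-trimmed gene body; genes with u_g == 0 cannot be evaluated for
    essentiality.
    """

    locus_tag: str
    start: int                 # 1-based inclusive (GFF3)
    end: int
    strand: str
    cogs: frozenset = frozenset()
    informative_flanks: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    u_g: int = 0
    evaluable: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.locus_tag}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_tag}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_gff3(path) -> list[GeneModel]:
    """Read gene features from GFF3; attributes locus_tag and optional cog."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        locus = feat.attributes.get("locus_tag", [feat.id])[0]
        raw = ",".join(feat.attributes.get("cog", []))
        cogs = frozenset(c for c in raw.replace(",", "") if c.strip())
        genes.append(
            GeneModel(
                locus_tag=locus,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                cogs=cogs,
            )
        )
    return genes


def assign_informative_sites(
    genes: list[GeneModel],
    genome: ReferenceGenome,
    flank_index: FlankIndex,
    trim_3prime: float = 0.1,
) -> list[GeneModel]:
    """Assign unique flanks to genes after a strand-aware 3'-terminal trim.

    A TA site belongs to a gene if its T position lies within the gene body
    minus the 3'-terminal ``trim_3prime`` fraction (insertions very close to
    a gene's 3' end often leave a functional product, so those sites are not
    informative about essentiality).  Overlapping genes may share sites; no
    arbitration is attempted.  Genes are annotated in place and returned.
    """
    if not (0 <= trim_3prime < 1):
        raise ValueError(f"trim_3prime={trim_3prime} outside [0, 1)")
    for g in genes:
        s0, e0 = g.start - 1, g.end
        if s0 < 0 or e0 > genome.length:
            raise ValueError(
                f"gene {g.locus_tag} [{g.start}, {g.end}] outside genome of "
                f"length {genome.length}"
            )
        trim = int(np.floor(trim_3prime * (e0 - s0)))
        lo, hi = (s0, e0 - trim) if g.strand == "+" else (s0 + trim, e0)
        i0 = np.searchsorted(flank_index.site_pos, lo, side="left")
        i1 = np.searchsorted(flank_index.site_pos, hi, side="left")
        idx = np.arange(i0, i1, dtype=np.int64)
        g.informative_flanks = idx[flank_index.unique[i0:i1]]
        g.u_g = len(g.informative_flanks)
        g.evaluable = g.u_g > 0
    return genes


def gene_table(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_tag": [g.locus_tag for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "cog": ["".join(sorted(g.cogs)) for g in genes],
            "u_g": [g.u_g for g in genes],
            "evaluable": [int(g.evaluable) for g in genes],
        }
    )
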