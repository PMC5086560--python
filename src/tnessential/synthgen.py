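"""Synthetic Tn-seq data generator.

Emulates a gene-saturating mariner mutagenesis experiment: a random genome
with dense TA dinucleotide sites, non-overlapping genes (a fraction of them
essential, i.e. depleted of viable insertion mutants), several sequencing
libraries of different sizes, negative-binomially dispersed read counts with
a smooth genomic-position bias, low-count noise insertions, and barcoded
reads of the form <6-nt barcode><NN><genomic tag>.  Ground-truth labels are
returned for parameter-recovery testing.

All randomness is driven by ``SimulationConfig.seed``; identical configs
produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_index import (
    FlankIndex,
    GeneModel,
    ReferenceGenome,
    build_flank_index,
    revcomp,
)

logger = logging.getLogger(__name__)

#: COG functional categories assigned to synthetic genes.
COG_CATEGORIES = tuple("CDEFGHIJKLMNOPQRSTUV")

#: Illumina-style 6-nt barcodes used by the Tn-seq adapter primers.
DEFAULT_BARCODES = ("ATCACG", "CGATGT", "TGACCA", "CTTGTA", "CGTACG")


class PackingError(ValueError):
    """Raised when the requested genes cannot be placed without overlap."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the real experiment's scale divided by ~10 so the whole
    pipeline runs in seconds: a 0.5 Mb replicon, ~400 genes of mean length
    1 kb, 10% essential, N=5,600 unique insertion mutants, three libraries
    of unequal depth, mean 300 reads per true insertion with NB dispersion
    0.3 (variance = mu + phi*mu^2), 5% of hit sites being 1-2-read noise,
    and a 2-fold sinusoidal position bias across the replicon.
    """

    genome_length: int = 500_000
    gc_content: float = 0.60
    n_genes: int = 400
    mean_gene_length: int = 1000
    essential_fraction: float = 0.10
    n_unique_mutants: int = 5600
    reads_mean: float = 300.0
    nb_dispersion: float = 0.30
    noise_site_fraction: float = 0.05
    noise_reads_max: int = 2
    position_bias_amplitude: float = 2.0
    n_libraries: int = 3
    barcodes: tuple = ()
    essential_depletion: float = 0.0   # 0 = hard model (no insertions in essentials)
    restrict_to_unique_flank_sites: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("gc_content", "essential_fraction", "noise_site_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.essential_depletion < 1.0):
            raise ValueError("essential_depletion must be in [0, 1)")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.position_bias_amplitude < 1.0:
            raise ValueError("position_bias_amplitude is a peak/trough fold >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not self.barcodes:
            if self.n_libraries > len(DEFAULT_BARCODES):
                raise ValueError(
                    f"only {len(DEFAULT_BARCODES)} default barcodes; pass "
                    f"barcodes explicitly for {self.n_libraries} libraries"
                )
            object.__setattr__(
                self, "barcodes", DEFAULT_BARCODES[: self.n_libraries]
            )
        if len(self.barcodes) != self.n_libraries:
            raise ValueError("need exactly one barcode per library")

    @property
    def library_names(self) -> list[str]:
        return [f"lib_{bc}" for bc in self.barcodes]

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "barcodes" in d and d["barcodes"]:
            d["barcodes"] = tuple(d["barcodes"])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment."""

    gene_essential: pd.Series          # bool, indexed by locus_tag
    site_true: pd.Series               # bool, indexed by TA position
    site_mean: pd.Series               # expected reads per site (0 if not hit)
    config: SimulationConfig


def position_bias(positions, genome_length: int, amplitude: float) -> np.ndarray:
    """Smooth multiplicative position bias: one sinusoidal period across the
    replicon with peak/trough fold = ``amplitude`` (mimics the
    origin-of-replication copy-number gradient that Loess correction
    targets)."""
    positions = np.asarray(positions, dtype=float)
    if amplitude == 1.0:
        return np.ones_like(positions)
    return amplitude ** (0.5 * np.sin(2 * np.pi * positions / genome_length))


def simulate_genome(config: SimulationConfig):
    """Random genome at the requested GC content plus non-overlapping genes.

    Every gene is guaranteed to contain at least one TA site (gene placement
    is resampled otherwise).  Returns (ReferenceGenome, list[GeneModel]).
    """
    rng = np.random.default_rng([config.seed, 0])
    at = (1.0 - config.gc_content) / 2.0
    gc = config.gc_content / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=config.genome_length,
                       p=[at, gc, gc, at])
    genome = ReferenceGenome.build("synth_chr1", "".join(bases))

    lengths = rng.gamma(shape=4.0, scale=config.mean_gene_length / 4.0,
                        size=config.n_genes)
    lengths = np.clip(np.round(lengths).astype(int), 150, None)
    slack = config.genome_length - int(lengths.sum())
    if slack < config.n_genes + 1:
        raise PackingError(
            f"cannot place {config.n_genes} genes totalling {lengths.sum()} bp "
            f"without overlap in a {config.genome_length} bp genome"
        )
    ta = genome.ta_positions
    for _ in range(100):
        gaps = rng.multinomial(slack, np.full(config.n_genes + 1, 1.0 / (config.n_genes + 1)))
        starts = np.cumsum(gaps[:-1]) + np.cumsum(np.concatenate([[0], lengths[:-1]]))
        ends = starts + lengths  # 0-based half-open
        # every gene must contain >= 1 TA site
        has_ta = np.searchsorted(ta, ends - 1, "left") > np.searchsorted(ta, starts, "left")
        if has_ta.all():
            break
    else:
        raise PackingError(
            "could not place genes so that every gene contains a TA site "
            "(genome too short or TA density too low)"
        )
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)
    primary = rng.choice(np.array(COG_CATEGORIES), size=config.n_genes)
    second = rng.choice(np.array(COG_CATEGORIES), size=config.n_genes)
    has_second = rng.random(config.n_genes) < 0.15
    genes = []
    for i in range(config.n_genes):
        cogs = {primary[i]}
        if has_second[i]:
            cogs.add(second[i])
        genes.append(
            GeneModel(
                locus_tag=f"HSYN_{i + 1:04d}",
                start=int(starts[i]) + 1,
                end=int(ends[i]),
                strand=str(strands[i]),
                cogs=frozenset(cogs),
            )
        )
    return genome, genes


def simulate_library(
    genome: ReferenceGenome,
    genes: list[GeneModel],
    config: SimulationConfig,
    flank_index: FlankIndex | None = None,
):
    """Sample unique insertion mutants and their read counts.

    True insertions are drawn uniformly without replacement from TA sites
    outside essential genes (hard model; ``essential_depletion`` > 0 admits
    them at a reduced rate).  Read counts per site follow
    NB(reads_mean x bias(pos), nb_dispersion) and are split across libraries
    of unequal depth by a per-site multinomial.  Noise sites (uniform over
    all TA sites, including essential genes) receive 1..noise_reads_max
    reads.  Returns (site x library count DataFrame, SimulationTruth).
    """
    rng = np.random.default_rng([config.seed, 1])
    if flank_index is None:
        flank_index = build_flank_index(genome, k=16)
    ta = genome.ta_positions
    n_sites = len(ta)

    ess_flags = rng.random(len(genes)) < config.essential_fraction
    in_essential = np.zeros(n_sites, dtype=bool)
    for g, is_ess in zip(genes, ess_flags):
        if is_ess:
            i0 = np.searchsorted(ta, g.start - 1, "left")
            i1 = np.searchsorted(ta, g.end, "left")
            in_essential[i0:i1] = True

    if config.restrict_to_unique_flank_sites:
        per_site = np.zeros(n_sites, dtype=int)
        site_idx_of_flank = np.searchsorted(ta, flank_index.site_pos)
        np.add.at(per_site, site_idx_of_flank, flank_index.unique.astype(int))
        n_flanks_site = np.zeros(n_sites, dtype=int)
        np.add.at(n_flanks_site, site_idx_of_flank, 1)
        candidate = (per_site == 2) & (n_flanks_site == 2)
    else:
        candidate = np.ones(n_sites, dtype=bool)

    weights = np.where(in_essential, config.essential_depletion, 1.0) * candidate
    n_avail = int((weights > 0).sum())
    if config.n_unique_mutants > n_avail:
        raise ValueError(
            f"n_unique_mutants={config.n_unique_mutants} exceeds the "
            f"{n_avail} available TA sites outside essential genes"
        )
    true_idx = rng.choice(
        n_sites, size=config.n_unique_mutants, replace=False, p=weights / weights.sum()
    )
    true_idx = np.sort(true_idx)

    mu = config.reads_mean * position_bias(ta[true_idx], genome.length,
                                           config.position_bias_amplitude)
    if config.nb_dispersion > 0:
        size = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)

    # noise sites: fraction of all hit sites, uniform over remaining TA sites
    nsf = config.noise_site_fraction
    n_noise = int(round(nsf / (1.0 - nsf) * config.n_unique_mutants)) if nsf > 0 else 0
    pool = np.setdiff1d(np.arange(n_sites), true_idx, assume_unique=False)
    n_noise = min(n_noise, len(pool))
    noise_idx = np.sort(rng.choice(pool, size=n_noise, replace=False))
    noise_counts = rng.integers(1, config.noise_reads_max + 1, size=n_noise)

    all_idx = np.concatenate([true_idx, noise_idx])
    all_counts = np.concatenate([counts, noise_counts])
    order = np.argsort(all_idx, kind="stable")
    all_idx, all_counts = all_idx[order], all_counts[order]

    lib_w = np.arange(1, config.n_libraries + 1, dtype=float)
    lib_w /= lib_w.sum()
    split = rng.multinomial(all_counts.astype(np.int64), lib_w)

    matrix = pd.DataFrame(split, index=pd.Index(ta[all_idx], name="position"),
                          columns=config.library_names)

    site_true = pd.Series(False, index=pd.Index(ta, name="position"))
    site_true.iloc[true_idx] = True
    site_mean = pd.Series(0.0, index=site_true.index)
    site_mean.iloc[true_idx] = mu
    truth = SimulationTruth(
        gene_essential=pd.Series(ess_flags, index=[g.locus_tag for g in genes]),
        site_true=site_true,
        site_mean=site_mean,
        config=config,
    )
    return matrix, truth


def site_to_flank_counts(
    site_matrix: pd.DataFrame,
    flank_index: FlankIndex,
    seed: int = 0,
) -> pd.DataFrame:
    """Split per-site counts onto the site's two flanks (binomial p=0.5),
    emulating which side of the insertion each fragment was sequenced from.
    Rows = flank indices into ``flank_index`` (all flanks, zeros included)."""
    rng = np.random.default_rng([seed, 2])
    out = np.zeros((flank_index.n_flanks, site_matrix.shape[1]), dtype=np.int64)
    pos_to_flanks: dict[int, list[int]] = {}
    for i, p in enumerate(flank_index.site_pos):
        pos_to_flanks.setdefault(int(p), []).append(i)
    for pos, row in site_matrix.iterrows():
        flanks = pos_to_flanks.get(int(pos), [])
        if not flanks:
            continue
        for j, c in enumerate(row.to_numpy()):
            if c == 0:
                continue
            if len(flanks) == 1:
                out[flanks[0], j] += c
            else:
                left = rng.binomial(int(c), 0.5)
                out[flanks[0], j] += left
                out[flanks[1], j] += int(c) - left
    return pd.DataFrame(out, columns=site_matrix.columns)


def emit_fastq(
    site_matrix: pd.DataFrame,
    genome: ReferenceGenome,
    barcodes,
    tag_length: int = 16,
    error_rate: float = 0.0,
    seed: int = 0,
    out=None,
):
    """Write one read per sequenced fragment: barcode + NN + genomic tag.

    The tag is the flank of the insertion's TA site on a uniformly chosen
    side, with per-base substitution errors at ``error_rate``.  Sites too
    close to a sequence end for a full flank on both sides are skipped with
    a logged warning; returns {"written": n, "skipped": n}.
    """
    if tag_length < 10:
        raise ValueError("tag_length must be >= 10")
    rng = np.random.default_rng([seed, 3])
    seq = genome.sequence
    n = len(seq)
    close_own = False
    if isinstance(out, (str, Path)):
        handle = open(out, "w")
        close_own = True
    else:
        handle = out
    bases = np.array(list("ACGT"))
    written = skipped = 0
    qual = "I" * (6 + 2 + tag_length)
    try:
        for j, (lib, bc) in enumerate(zip(site_matrix.columns, barcodes)):
            col = site_matrix[lib].to_numpy()
            for pos, c in zip(site_matrix.index.to_numpy(), col):
                c = int(c)
                if c == 0:
                    continue
                pos = int(pos)
                if pos < tag_length or pos + 2 + tag_length > n:
                    logger.warning(
                        "site %d too close to a sequence end for a %d-nt flank; "
                        "skipping %d reads", pos, tag_length, c)
                    skipped += c
                    continue
                left = revcomp(seq[pos - tag_length : pos])
                right = seq[pos + 2 : pos + 2 + tag_length]
                sides = rng.integers(0, 2, size=c)
                nn = rng.choice(bases, size=(c, 2))
                for i in range(c):
                    tag = right if sides[i] else left
                    if error_rate > 0:
                        tl = list(tag)
                        for b in np.nonzero(rng.random(tag_length) < error_rate)[0]:
                            choices = [x for x in "ACGT" if x != tl[b]]
                            tl[b] = choices[rng.integers(0, 3)]
                        tag = "".join(tl)
                    read = bc + nn[i, 0] + nn[i, 1] + tag
                    handle.write(f"@{lib}:{pos}:{i}\n{read}\n+\n{qual}\n")
                    written += 1
    finally:
        if close_own:
            handle.close()
    return {"written": written, "skipped": skipped}


def write_fasta(genome: ReferenceGenome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_gff3(genes: list[GeneModel], genome: ReferenceGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for g in genes:
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.cogs:
                attrs += f";cog={','.join(sorted(g.cogs))}"
            fh.write(
                f"{genome.id}\ttnessential_synthgen\tgene\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_truth_tsv(truth: SimulationTruth, site_matrix: pd.DataFrame,
                    genes: list[GeneModel], path) -> None:
    """Per-site truth table: position, containing gene, true flag, counts."""
    hit = site_matrix.copy()
    pos = hit.index.to_numpy()
    locus = np.full(len(pos), "", dtype=object)
    for g in genes:
        inside = (pos >= g.start - 1) & (pos < g.end)
        locus[inside] = g.locus_tag
    out = pd.DataFrame({"position": pos, "gene": locus,
                        "true_insertion": truth.site_true.loc[pos].astype(int).to_numpy()})
    for c in hit.columns:
        out[c] = hit[c].to_numpy()
    out.to_csv(path, sep="\t", index=False)
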