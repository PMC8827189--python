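"""Genome composition indexes.

Computes, from an annotated genome (FASTA sequence + GFF3-style features),
the GC-content indexes analysed throughout this package: whole-genome GC
(GC_w), protein-coding GC (GC_p), GC at fourfold-degenerate third codon
positions (GC_4), GC of unannotated DNA (GC_non, intergenic + UTR), GC of
the structural RNA genes (tRNA, 5S/16S/23S rRNA), per-replicon-class
(chromosome vs plasmid) variants, and reverse-complement-pooled
dinucleotide class frequencies.  Also houses the growth-temperature rank
classification and the core/accessory gene-family partition.

Coordinates are 1-based closed (the GFF3 convention); conversion to
0-based half-open happens exactly once, at the parser boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("CDS", "tRNA", "rRNA_5S", "rRNA_16S", "rRNA_23S", "other_RNA")
REPLICON_CLASSES = ("chromosome", "plasmid")

#: Codon families whose third position is fourfold degenerate under
#: translation table 11 (first two bases shown; any third base keeps the
#: amino acid): Leu CTN, Val GTN, Ser TCN, Pro CCN, Thr ACN, Ala GCN,
#: Arg CGN, Gly GGN.
FOURFOLD_PREFIXES = frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})

STOP_CODONS_TABLE11 = frozenset({"TAA", "TAG", "TGA"})

#: The 16 dinucleotides pooled into 10 reverse-complement classes, keyed by
#: the conventional class name, e.g. "AG(CT)" pools AG with its reverse
#: complement CT.
DINUC_CLASSES: dict[str, tuple[str, ...]] = {
    "AA(TT)": ("AA", "TT"),
    "AC(GT)": ("AC", "GT"),
    "AG(CT)": ("AG", "CT"),
    "AT": ("AT",),
    "CA(TG)": ("CA", "TG"),
    "CC(GG)": ("CC", "GG"),
    "CG": ("CG",),
    "GA(TC)": ("GA", "TC"),
    "GC": ("GC",),
    "TA": ("TA",),
}

RANK_NAMES = {1: "psychrophile/psychrotrophile", 2: "mesophile",
              3: "thermophile", 4: "hyperthermophile"}


@dataclass
class Feature:
    """One annotated feature; ``start``/``end`` are 1-based closed."""

    replicon_id: str
    type: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"feature type {self.type!r} not in {FEATURE_TYPES}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class Replicon:
    id: str
    klass: str
    seq: str

    def __post_init__(self) -> None:
        if self.klass not in REPLICON_CLASSES:
            raise ValueError(f"replicon class {self.klass!r} not in {REPLICON_CLASSES}")


@dataclass
class AnnotatedGenome:
    genome_id: str
    replicons: list[Replicon]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError("genome must have at least one replicon")
        by_id = {r.id: r for r in self.replicons}
        if len(by_id) != len(self.replicons):
            raise ValueError("duplicate replicon ids")
        for f in self.features:
            rep = by_id.get(f.replicon_id)
            if rep is None:
                raise ValueError(f"feature on unknown replicon {f.replicon_id!r}")
            if f.end > len(rep.seq):
                raise ValueError(
                    f"feature {f.type} {f.start}..{f.end} extends past end of "
                    f"replicon {f.replicon_id!r} (length {len(rep.seq)})")

    def feature_seq(self, f: Feature) -> str:
        """Strand-corrected feature sequence (coding strand for CDS)."""
        rep = next(r for r in self.replicons if r.id == f.replicon_id)
        s = rep.seq[f.start - 1:f.end]
        return str(Seq(s).reverse_complement()) if f.strand == "-" else s


@dataclass
class CompositionProfile:
    """Per-genome GC indexes (percent) and dinucleotide class frequencies.

    Indexes that cannot be computed (no CDS, no 5S gene, no plasmid...)
    are NaN, never 0.
    """

    genome_id: str
    gc_w: float = math.nan
    gc_p: float = math.nan
    gc_4: float = math.nan
    gc_non: float = math.nan
    gc_trna: float = math.nan
    gc_5s: float = math.nan
    gc_16s: float = math.nan
    gc_23s: float = math.nan
    by_replicon_class: dict[str, dict[str, float]] = field(default_factory=dict)
    dinucleotide_freqs: dict[str, float] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)

    def to_row(self) -> dict[str, float]:
        row = {"genome": self.genome_id, "GC_w": self.gc_w, "GC_p": self.gc_p,
               "GC_4": self.gc_4, "GC_non": self.gc_non, "GC_tRNA": self.gc_trna,
               "GC_5S": self.gc_5s, "GC_16S": self.gc_16s, "GC_23S": self.gc_23s}
        for klass, d in self.by_replicon_class.items():
            for k, v in d.items():
                row[f"{k}_{klass}"] = v
        row.update(self.dinucleotide_freqs)
        return row


# ----------------------------------------------------------- GC fractions

def gc_fraction(seq: str) -> float:
    """GC percentage, ambiguity codes excluded from both counts.

    Returns NaN for an empty effective length (missing value, not zero).
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    tot = gc + at
    if tot == 0:
        return math.nan
    return 100.0 * gc / tot


def fourfold_site_gc(cds_sequences: list[str]) -> float:
    """GC percentage at fourfold-degenerate third codon positions.

    Each CDS must be in reading frame on the coding strand.  The final
    codon of each CDS is treated as the stop and excluded.  A third
    position is counted iff the codon's first two bases put it in a
    fourfold family under translation table 11.  CDS with length not
    divisible by 3, internal stop codons, or ambiguity in the first two
    positions of any codon are skipped with a log message.
    """
    if not cds_sequences:
        return math.nan
    gc = at = 0
    for idx, cds in enumerate(cds_sequences):
        s = cds.upper()
        if len(s) % 3 != 0:
            logger.info("CDS %d skipped: length %d not divisible by 3", idx, len(s))
            continue
        codons = [s[i:i + 3] for i in range(0, len(s) - 3, 3)]  # stop excluded
        if any(c in STOP_CODONS_TABLE11 for c in codons):
            logger.info("CDS %d skipped: internal stop codon", idx)
            continue
        if any(ch not in "ACGT" for c in codons for ch in c[:2]):
            logger.info("CDS %d skipped: ambiguity in codon positions 1-2", idx)
            continue
        for c in codons:
            if c[:2] in FOURFOLD_PREFIXES:
                b = c[2]
                if b in "GC":
                    gc += 1
                elif b in "AT":
                    at += 1
    tot = gc + at
    return math.nan if tot == 0 else 100.0 * gc / tot


def dinucleotide_class_freqs(genome: AnnotatedGenome | list[str]) -> dict[str, float]:
    """Frequencies of the 10 reverse-complement dinucleotide classes.

    Overlapping windows on the given strand of each replicon, no
    wraparound; windows containing ambiguity are skipped.  Counting one
    strand and pooling by reverse-complement class equals double-strand
    counting up to edge effects.
    """
    seqs = ([r.seq for r in genome.replicons]
            if isinstance(genome, AnnotatedGenome) else list(genome))
    counts = {d: 0 for klass in DINUC_CLASSES.values() for d in klass}
    total = 0
    for seq in seqs:
        s = seq.upper()
        for i in range(len(s) - 1):
            d = s[i:i + 2]
            if d[0] in "ACGT" and d[1] in "ACGT":
                counts[d] += 1
                total += 1
    if total == 0:
        return {name: math.nan for name in DINUC_CLASSES}
    return {name: sum(counts[d] for d in members) / total
            for name, members in DINUC_CLASSES.items()}


# --------------------------------------------------------------- profiles

def _coverage_mask(length: int, feats: list[Feature]) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    for f in feats:
        m[f.start - 1:f.end] = True
    return m


def compute_profile(genome: AnnotatedGenome, translation_table: int = 11) -> CompositionProfile:
    """All GC indexes and dinucleotide class frequencies for one genome.

    GC_w concatenates all replicons; GC_p concatenates strand-corrected CDS;
    GC_non covers positions overlapped by no feature of any type on either
    strand (set semantics: a position under two features is excluded once);
    RNA indexes concatenate the features of each RNA type.  Chromosome-only
    and plasmid-only variants repeat GC_w/GC_p/GC_4/GC_non on the replicon
    subsets.
    """
    if translation_table != 11:
        raise NotImplementedError("only translation table 11 is supported")
    prof = CompositionProfile(genome.genome_id)
    prof.gc_w = gc_fraction("".join(r.seq for r in genome.replicons))
    prof.dinucleotide_freqs = dinucleotide_class_freqs(genome)

    def _indexes(replicons: list[Replicon]) -> dict[str, float]:
        ids = {r.id for r in replicons}
        feats = [f for f in genome.features if f.replicon_id in ids]
        cds = [genome.feature_seq(f) for f in feats if f.type == "CDS"]
        noncoding = []
        for r in replicons:
            mask = _coverage_mask(len(r.seq), [f for f in feats if f.replicon_id == r.id])
            noncoding.append("".join(ch for ch, cov in zip(r.seq, mask) if not cov))
        return {
            "GC_w": gc_fraction("".join(r.seq for r in replicons)),
            "GC_p": gc_fraction("".join(cds)) if cds else math.nan,
            "GC_4": fourfold_site_gc(cds),
            "GC_non": gc_fraction("".join(noncoding)),
        }

    whole = _indexes(genome.replicons)
    prof.gc_p, prof.gc_4, prof.gc_non = whole["GC_p"], whole["GC_4"], whole["GC_non"]
    rna_types = {"tRNA": "gc_trna", "rRNA_5S": "gc_5s",
                 "rRNA_16S": "gc_16s", "rRNA_23S": "gc_23s"}
    for ftype, attr in rna_types.items():
        seqs = [genome.feature_seq(f) for f in genome.features if f.type == ftype]
        if seqs:
            setattr(prof, attr, gc_fraction("".join(seqs)))
        else:
            prof.missing.append(ftype)
    for klass in REPLICON_CLASSES:
        reps = [r for r in genome.replicons if r.klass == klass]
        if reps:
            prof.by_replicon_class[klass] = _indexes(reps)
        else:
            prof.missing.append(f"no_{klass}")
    return prof


# -------------------------------------------------- temperature categories

def classify_topt(topt: float) -> int:
    """Growth-temperature rank from Topt (deg C).

    1 = psychrophile/psychrotrophile (Topt < 20), 2 = mesophile
    (20 <= Topt < 45), 3 = thermophile (45 <= Topt < 80),
    4 = hyperthermophile (Topt >= 80).
    """
    if not math.isfinite(topt):
        raise ValueError("Topt must be finite")
    if topt < 20.0:
        return 1
    if topt < 45.0:
        return 2
    if topt < 80.0:
        return 3
    return 4


# ------------------------------------------------------- core / accessory

def core_accessory_sets(presence: pd.DataFrame, core_fraction: float = 1.0,
                        accessory_fraction: float = 0.05) -> tuple[list[str], list[str]]:
    """Split gene families into core and accessory sets.

    ``presence`` is a genomes x families 0/1 matrix.  Core: presence
    fraction >= ``core_fraction``; accessory: fraction < ``accessory_fraction``.
    The sets are disjoint whenever ``accessory_fraction <= core_fraction``.
    """
    if presence.size == 0:
        raise ValueError("empty presence/absence matrix")
    vals = presence.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    frac = vals.mean(axis=0)
    core = [c for c, f in zip(presence.columns, frac) if f >= core_fraction]
    accessory = [c for c, f in zip(presence.columns, frac) if f < accessory_fraction]
    return core, accessory


# ------------------------------------------------------------ file parsing

_GFF_TYPE_MAP = {"CDS": "CDS", "tRNA": "tRNA"}


def _rrna_type(product: str) -> str:
    p = product.lower()
    if "5s" in p:
        return "rRNA_5S"
    if "16s" in p:
        return "rRNA_16S"
    if "23s" in p:
        return "rRNA_23S"
    return "other_RNA"


def read_genome(fasta_path: str | Path, gff_path: str | Path,
                genome_id: str | None = None,
                replicon_classes: dict[str, str] | None = None) -> AnnotatedGenome:
    """Load an annotated genome from FASTA + GFF3 files.

    rRNA features are typed from their ``product`` attribute (5S/16S/23S);
    replicon classes default to "chromosome" unless the FASTA description
    or ``replicon_classes`` says "plasmid".
    """
    import gffutils

    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    replicons = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        klass = "plasmid" if "plasmid" in rec.description.lower() else "chromosome"
        if replicon_classes and rec.id in replicon_classes:
            klass = replicon_classes[rec.id]
        replicons.append(Replicon(rec.id, klass, str(rec.seq).upper()))
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    features = []
    for f in db.all_features():
        if f.featuretype in _GFF_TYPE_MAP:
            ftype = _GFF_TYPE_MAP[f.featuretype]
        elif f.featuretype == "rRNA":
            product = (f.attributes.get("product") or [""])[0]
            ftype = _rrna_type(product)
        elif f.featuretype in ("ncRNA", "tmRNA", "RNase_P_RNA", "SRP_RNA"):
            ftype = "other_RNA"
        else:
            continue
        features.append(Feature(f.seqid, ftype, f.start, f.end,
                                f.strand if f.strand in "+-" else "+"))
    gid = genome_id or fasta_path.stem
    return AnnotatedGenome(gid, replicons, features)


def profiles_to_frame(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """One row per genome, one column per index (TSV-ready)."""
    return pd.DataFrame([p.to_row() for p in profiles]).set_index("genome")
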