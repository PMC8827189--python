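"""Synthetic data with known truth for every pipeline stage.

Generates ultrametric birth-death trees, correlated (Topt, GC) trait
pairs evolving under bivariate Brownian motion with optional discrete
jumps and an optional high-GC outlier clade, toy annotated genomes whose
composition indexes hit stated targets, and gene-family presence/absence
matrices with planted core and accessory families.

Every generator is a pure function of its config and the master seed;
RNG substreams are keyed (seed, component, index) so adding one genome
never perturbs another.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from . import phylo
from .composition import AnnotatedGenome, CompositionProfile, Feature, Replicon, classify_topt
from .jumps import simulate_levy
from .phylo import PhyloTree

logger = logging.getLogger(__name__)

_COMPONENT = {"tree": 1, "traits": 2, "genome": 3, "presence": 4}

# Codon pools for CDS bodies (translation table 11).  H and M are fourfold
# families (third base free), split by GC of the first two bases; L are
# AT-only non-fourfold codons used to lower coding GC without touching
# GC_4.  None can form a stop codon.
_POOL_H = ("CC", "GC", "CG", "GG")   # first-two GC = 2
_POOL_M = ("CT", "GT", "TC", "AC")   # first-two GC = 1
_POOL_L = ("AAA", "AAT", "ATT", "TTT")

_RNA_LENGTHS = {"tRNA": 76, "rRNA_5S": 120, "rRNA_16S": 1500, "rRNA_23S": 2900}


@dataclass
class TraitConfig:
    Sigma: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    roots: tuple[float, float] = (0.0, 0.0)
    jump_lam: float = 0.0          # jump intensity on the GC trait
    jump_sigma2: float = 0.0
    outlier_clade_size: int = 0    # high-GC outlier clade (0 = none)
    outlier_gc_offset: float = 0.0
    topt_range: tuple[float, float] | None = (5.0, 105.0)
    gc_range: tuple[float, float] | None = (25.0, 75.0)


@dataclass
class GenomeConfig:
    n_cds: int = 100
    cds_len_codons: int = 120      # body codons (start/stop added)
    n_trna: int = 4
    n_5s: int = 1
    n_16s: int = 1
    n_23s: int = 1
    spacer_len: int = 200
    gc_4: float = 60.0
    gc_non: float = 45.0
    gc_rna: float = 58.0
    gc_w: float | None = None      # if set, coding GC is solved to hit it
    n_plasmids: int = 0
    plasmid_n_cds: int = 20
    plasmid_gc_offset: float = -8.0


@dataclass
class SyntheticConfig:
    n_tips: int = 100
    birth_rate: float = 1.0
    death_rate: float = 0.0
    traits: TraitConfig = field(default_factory=TraitConfig)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    n_core: int = 30
    n_accessory: int = 500
    n_mid_families: int = 100
    seed: int = 0


# ------------------------------------------------------------------ trees

def gen_tree(config: SyntheticConfig | None = None, n_tips: int | None = None,
             birth_rate: float = 1.0, death_rate: float = 0.0,
             seed: int | None = None) -> PhyloTree:
    """Ultrametric birth-death tree with unit depth, deterministic per seed."""
    if config is not None:
        n_tips, birth_rate, death_rate = config.n_tips, config.birth_rate, config.death_rate
        seed = config.seed if seed is None else seed
    if n_tips is None or n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    seed = 0 if seed is None else seed
    rng = random.Random(int(np.random.default_rng([seed, _COMPONENT["tree"]])
                            .integers(2 ** 31)))
    last = None
    for attempt in range(100):
        try:
            # Simulate one extra tip and drop the newest one: the simulator
            # stops at the n-th birth, which leaves twin tips on zero-length
            # branches and hence a singular covariance.
            dtree = treesim.birth_death_tree(
                birth_rate=birth_rate, death_rate=death_rate,
                num_extant_tips=n_tips + 1, rng=rng)
            break
        except Exception as exc:  # total extinction
            last = exc
            logger.info("birth-death attempt %d failed (%s); retrying", attempt + 1, exc)
    else:
        raise RuntimeError(f"tree simulation failed after 100 retries: {last}")
    newest = min(dtree.leaf_node_iter(), key=lambda nd: nd.edge.length or 0.0)
    dtree.prune_taxa([newest.taxon])
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    tree = PhyloTree(dtree)
    depth = max(nd._tgc_depth for nd in dtree.leaf_node_iter())
    for nd in dtree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length = nd.edge.length / depth
    return PhyloTree(dtree)


# ----------------------------------------------------------------- traits

def _affine_to(v: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, tuple[float, float]]:
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        return np.full_like(v, 0.5 * (lo + hi)), (0.0, 0.5 * (lo + hi))
    a = (hi - lo) / (vmax - vmin)
    b = lo - a * vmin
    return a * v + b, (a, b)


def gen_traits(tree: PhyloTree, config: TraitConfig | None = None,
               seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """(Topt, GC) tip traits under correlated BM, with truth record.

    Optional compound-Poisson jumps add to the GC trait; an optional
    constant GC offset marks the lowest-Topt clade of the requested size
    as a high-GC outlier group (the halophile pattern).  Traits are then
    affinely mapped into plausible measurement ranges; the maps, jump
    record, evolutionary covariance and outlier membership are returned
    as truth.
    """
    cfg = config or TraitConfig()
    Sigma = np.asarray(cfg.Sigma, dtype=float)
    X = phylo.simulate_traits(tree, Sigma, cfg.roots,
                              seed=np.random.default_rng([seed, _COMPONENT["traits"], 0]))[0]
    topt_raw, gc_raw = X[:, 0].copy(), X[:, 1].copy()
    labels = tree.tip_labels
    truth: dict = {"Sigma": Sigma, "jumps": None, "outlier_tips": [],
                   "topt_map": (1.0, 0.0), "gc_map": (1.0, 0.0)}

    if cfg.jump_lam > 0 and cfg.jump_sigma2 > 0:
        jump_tips, jtruth = simulate_levy(
            tree, 0.0, cfg.jump_lam, cfg.jump_sigma2, 0.0,
            seed=np.random.default_rng([seed, _COMPONENT["traits"], 1]))
        gc_raw = gc_raw + jump_tips.loc[labels].to_numpy()
        truth["jumps"] = jtruth

    if cfg.outlier_clade_size > 0 and cfg.outlier_gc_offset != 0.0:
        topt_by_tip = dict(zip(labels, topt_raw))
        best, best_key = None, None
        for nd in tree._tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            tips = [labels[i] for i in nd._tgc_tips]
            if len(tips) == tree.n_tips:
                continue
            size_gap = abs(len(tips) - cfg.outlier_clade_size)
            mean_topt = float(np.mean([topt_by_tip[t] for t in tips]))
            key = (size_gap, mean_topt)
            if best_key is None or key < best_key:
                best, best_key = tips, key
        sel = np.isin(labels, best)
        gc_raw = gc_raw + np.where(sel, cfg.outlier_gc_offset, 0.0)
        truth["outlier_tips"] = list(best)

    if cfg.topt_range is not None:
        topt, truth["topt_map"] = _affine_to(topt_raw, *cfg.topt_range)
    else:
        topt = topt_raw
    if cfg.gc_range is not None:
        gc, truth["gc_map"] = _affine_to(gc_raw, *cfg.gc_range)
    else:
        gc = gc_raw
    table = pd.DataFrame({"Topt": topt, "GC": gc,
                          "rank": [classify_topt(t) for t in topt]},
                         index=pd.Index(labels, name="tip"))
    return table, truth


# ---------------------------------------------------------------- genomes

def _exact_gc_seq(rng: np.random.Generator, length: int, gc_percent: float) -> str:
    """Random sequence whose GC count is exactly round(target * length)."""
    n_gc = int(round(gc_percent / 100.0 * length))
    is_gc = np.zeros(length, dtype=bool)
    is_gc[rng.permutation(length)[:n_gc]] = True
    gc_choices = rng.choice(list("GC"), size=length)
    at_choices = rng.choice(list("AT"), size=length)
    return "".join(np.where(is_gc, gc_choices, at_choices))


def _solve_codon_mix(gc_w: float | None, theta: float, cfg: GenomeConfig) -> tuple[float, float, float]:
    """Pool fractions (h, m, l) so the assembled chromosome hits gc_w.

    With no gc_w target the mix is h = m = 0.5.  theta is the fourfold
    third-position GC fraction (the GC_4 target / 100).
    """
    if gc_w is None:
        return 0.5, 0.5, 0.0
    nb = cfg.cds_len_codons
    n_genes = (cfg.n_cds + cfg.n_trna + cfg.n_5s + cfg.n_16s + cfg.n_23s)
    rna_len = (cfg.n_trna * _RNA_LENGTHS["tRNA"] + cfg.n_5s * _RNA_LENGTHS["rRNA_5S"]
               + cfg.n_16s * _RNA_LENGTHS["rRNA_16S"] + cfg.n_23s * _RNA_LENGTHS["rRNA_23S"])
    sp_len = (n_genes + 1) * cfg.spacer_len
    total = cfg.n_cds * (6 + 3 * nb) + rna_len + sp_len
    gc_needed = (gc_w / 100.0 * total
                 - cfg.n_cds                      # ATG contributes 1, TAA 0
                 - rna_len * cfg.gc_rna / 100.0
                 - sp_len * cfg.gc_non / 100.0)
    g_b = gc_needed / (cfg.n_cds * nb)            # GC bases per body codon
    lo = 0.0  # all-L mix
    if g_b < 0 or g_b > 2.0 + theta:
        raise ValueError(f"gc_w target {gc_w} infeasible (needs {g_b:.2f} "
                         f"GC bases per codon)")
    if g_b >= 1.0 + theta:         # l = 0; g_b = 1 + h + theta
        h = min(g_b - 1.0 - theta, 1.0)
        return h, 1.0 - h, 0.0
    m = g_b / (1.0 + theta)        # h = 0; g_b = m (1 + theta)
    l = 1.0 - m
    if l > 0.95:
        raise ValueError("gc_w target leaves too few fourfold codons")
    return 0.0, m, l


def _make_cds_batch(rng: np.random.Generator, n_cds: int, nb: int,
                    theta: float, h: float, m: float, l: float) -> list[str]:
    """CDS sequences with genome-wide exact pool and third-position counts."""
    total = n_cds * nb
    n_h = int(round(h * total))
    n_l = int(round(l * total))
    n_m = total - n_h - n_l
    pools = np.concatenate([np.zeros(n_h, np.int8), np.ones(n_m, np.int8),
                            2 * np.ones(n_l, np.int8)])
    rng.shuffle(pools)
    n_ff = n_h + n_m
    thirds_gc = np.zeros(n_ff, dtype=bool)
    thirds_gc[rng.permutation(n_ff)[: int(round(theta * n_ff))]] = True
    gc_third = rng.choice(list("GC"), size=n_ff)
    at_third = rng.choice(list("AT"), size=n_ff)
    prefixes_h = rng.choice(_POOL_H, size=max(n_h, 1))
    prefixes_m = rng.choice(_POOL_M, size=max(n_m, 1))
    l_codons = rng.choice(_POOL_L, size=max(n_l, 1))
    out, ih, im, il, iff = [], 0, 0, 0, 0
    for _ in range(n_cds):
        codons = ["ATG"]
        for _ in range(nb):
            pool = pools[ih + im + il]
            if pool == 2:
                codons.append(l_codons[il]); il += 1
            else:
                pref = prefixes_h[ih] if pool == 0 else prefixes_m[im]
                third = gc_third[iff] if thirds_gc[iff] else at_third[iff]
                codons.append(pref + third)
                iff += 1
                if pool == 0:
                    ih += 1
                else:
                    im += 1
        codons.append("TAA")
        out.append("".join(codons))
    return out


def _assemble_replicon(rng: np.random.Generator, rep_id: str, klass: str,
                       genes: list[tuple[str, str]], spacer_len: int,
                       gc_non: float) -> tuple[Replicon, list[Feature]]:
    """Interleave genes with exact-GC spacers; alternate strands for CDS."""
    parts, feats = [], []
    pos = 0
    order = rng.permutation(len(genes))
    for j, gi in enumerate(order):
        sp = _exact_gc_seq(rng, spacer_len, gc_non)
        parts.append(sp)
        pos += spacer_len
        ftype, seq = genes[gi]
        strand = "+"
        if ftype == "CDS" and j % 2 == 1:
            strand = "-"
            from Bio.Seq import Seq
            seq_on_genome = str(Seq(seq).reverse_complement())
        else:
            seq_on_genome = seq
        parts.append(seq_on_genome)
        feats.append(Feature(rep_id, ftype, pos + 1, pos + len(seq), strand))
        pos += len(seq)
    parts.append(_exact_gc_seq(rng, spacer_len, gc_non))
    return Replicon(rep_id, klass, "".join(parts)), feats


def gen_genome(config: GenomeConfig | None = None, genome_id: str = "g1",
               seed: int = 0) -> tuple[AnnotatedGenome, CompositionProfile]:
    """Toy annotated genome hitting the configured composition targets.

    Returns the genome and its generation-truth profile (targets; GC_w
    recomputed from the assembled sequence).  All sites are placed with
    exact counts, so a round trip through the profiler recovers each
    target to well under one percentage point.
    """
    cfg = config or GenomeConfig()
    theta = cfg.gc_4 / 100.0
    if cfg.n_cds * cfg.cds_len_codons < 40:
        raise ValueError("too few codons to hit a GC_4 target")
    h, m, l = _solve_codon_mix(cfg.gc_w, theta, cfg)
    rng = np.random.default_rng([seed, _COMPONENT["genome"], 0])
    cds = _make_cds_batch(rng, cfg.n_cds, cfg.cds_len_codons, theta, h, m, l)
    genes: list[tuple[str, str]] = [("CDS", s) for s in cds]
    for ftype, count in (("tRNA", cfg.n_trna), ("rRNA_5S", cfg.n_5s),
                         ("rRNA_16S", cfg.n_16s), ("rRNA_23S", cfg.n_23s)):
        for _ in range(count):
            genes.append((ftype, _exact_gc_seq(rng, _RNA_LENGTHS[ftype], cfg.gc_rna)))
    chrom, feats = _assemble_replicon(rng, f"{genome_id}_chr", "chromosome",
                                      genes, cfg.spacer_len, cfg.gc_non)
    replicons, features = [chrom], feats
    for p in range(cfg.n_plasmids):
        prng = np.random.default_rng([seed, _COMPONENT["genome"], 1 + p])
        theta_p = min(max(theta + cfg.plasmid_gc_offset / 100.0, 0.0), 1.0)
        pcds = _make_cds_batch(prng, cfg.plasmid_n_cds, cfg.cds_len_codons,
                               theta_p, h, m, l)
        rep, pf = _assemble_replicon(
            prng, f"{genome_id}_p{p+1}", "plasmid", [("CDS", s) for s in pcds],
            cfg.spacer_len, min(max(cfg.gc_non + cfg.plasmid_gc_offset, 0.0), 100.0))
        replicons.append(rep)
        features.extend(pf)
    genome = AnnotatedGenome(genome_id, replicons, features)
    from .composition import gc_fraction
    truth = CompositionProfile(
        genome_id,
        gc_w=gc_fraction("".join(r.seq for r in replicons)),
        gc_4=cfg.gc_4, gc_non=cfg.gc_non,
        gc_trna=cfg.gc_rna if cfg.n_trna else math.nan,
        gc_5s=cfg.gc_rna if cfg.n_5s else math.nan,
        gc_16s=cfg.gc_rna if cfg.n_16s else math.nan,
        gc_23s=cfg.gc_rna if cfg.n_23s else math.nan,
    )
    return genome, truth


def write_genome(genome: AnnotatedGenome, fasta_path: str | Path,
                 gff_path: str | Path) -> None:
    """Emit FASTA and GFF3 (rRNA typed via ``product`` attributes)."""
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    with open(fasta_path, "w") as fh:
        for r in genome.replicons:
            desc = " plasmid" if r.klass == "plasmid" else ""
            fh.write(f">{r.id}{desc}\n")
            for i in range(0, len(r.seq), 70):
                fh.write(r.seq[i:i + 70] + "\n")
    type_out = {"CDS": ("CDS", None), "tRNA": ("tRNA", None),
                "rRNA_5S": ("rRNA", "5S ribosomal RNA"),
                "rRNA_16S": ("rRNA", "16S ribosomal RNA"),
                "rRNA_23S": ("rRNA", "23S ribosomal RNA"),
                "other_RNA": ("ncRNA", None)}
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(genome.features, 1):
            gtype, product = type_out[f.type]
            attrs = f"ID=feat{i}"
            if product:
                attrs += f";product={product}"
            fh.write("\t".join([f.replicon_id, "thermogc", gtype, str(f.start),
                                str(f.end), ".", f.strand, "0" if gtype == "CDS" else ".",
                                attrs]) + "\n")


# ------------------------------------------------------- presence matrices

def gen_presence_matrix(n_genomes: int, n_core: int = 30, n_accessory: int = 500,
                        n_mid: int = 100, accessory_fraction: float = 0.05,
                        seed: int = 0) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Genome x family 0/1 matrix with planted core/mid/accessory families.

    Core families are present everywhere; accessory families in strictly
    fewer than ``accessory_fraction`` of genomes (at least one); mid
    families strictly between the two thresholds.
    """
    rng = np.random.default_rng([seed, _COMPONENT["presence"]])
    genomes = [f"g{i+1}" for i in range(n_genomes)]
    cols, data = [], []
    truth = {"core": [], "accessory": [], "mid": []}
    acc_max = max(int(math.ceil(accessory_fraction * n_genomes)) - 1, 1)
    mid_min = int(math.floor(accessory_fraction * n_genomes)) + 1
    for i in range(n_core):
        cols.append(f"core{i+1}"); truth["core"].append(cols[-1])
        data.append(np.ones(n_genomes, dtype=int))
    for i in range(n_accessory):
        cols.append(f"acc{i+1}"); truth["accessory"].append(cols[-1])
        k = int(rng.integers(1, acc_max + 1))
        row = np.zeros(n_genomes, dtype=int)
        row[rng.permutation(n_genomes)[:k]] = 1
        data.append(row)
    for i in range(n_mid):
        cols.append(f"mid{i+1}"); truth["mid"].append(cols[-1])
        k = int(rng.integers(mid_min, n_genomes))  # < n, so never core
        row = np.zeros(n_genomes, dtype=int)
        row[rng.permutation(n_genomes)[:k]] = 1
        data.append(row)
    mat = pd.DataFrame(np.array(data).T, index=pd.Index(genomes, name="genome"),
                       columns=cols)
    return mat, truth
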