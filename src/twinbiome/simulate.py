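"""Synthetic twin-cohort generator.

Produces, deterministically from a :class:`~twinbiome.config.SimConfig`, a
metadata table of MZ/DZ twin pairs and unrelated singletons, phased tag-SNP
and background genotypes (with MZ co-twins genetically identical and DZ
co-twins sharing parental transmissions), a rooted bifurcating OTU tree with
nested taxonomy, and a multinomial OTU count table whose latent
log-abundances carry family-shared and additive-genetic components so that
microbiome similarity orders MZ pairs < DZ pairs < unrelated pairs.

Counts are drawn multinomially from the softmax of Gaussian latent
log-abundances (a log-normal-like compositional model); DZ sharing arises
from explicit parental haplotype transmission and mid-parent additive
values, so genotype sharing and microbiome sharing are jointly coherent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .config import (ABO_TAG_SNPS, LCT_SNP, SECRETOR_SNP, SimConfig)
from .genotypes import (HaplotypeTable, PhasedGenotypes, abo_phenotype,
                        call_secretor, default_haplotype_table)
from .otu import OtuTable, RANKS

# distinct RNG streams per stage so each stage is reproducible on its own
_STAGE = {"cohort": 1, "genotypes": 2, "tree": 3, "otu": 4, "phenotyping": 5}


def _rng(config_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], config_seed])


# ---------------------------------------------------------------------------
# cohort metadata

def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Sample metadata table indexed by sample ID.

    MZ/DZ family IDs appear exactly twice, singleton family IDs once;
    zygosity is constant within family. Covariates: sex ~ Bernoulli(male
    fraction), age ~ Normal, BMI ~ Normal, sequencing depth ~ negative
    binomial, shipment batch and technician categorical.
    """
    config.validate()
    rng = _rng(config.seed, "cohort")
    rows = []
    fam = 0
    for zyg, n_pairs in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        for _ in range(n_pairs):
            fid = f"F{fam:05d}"
            for member in (1, 2):
                rows.append((f"{fid}_{member}", fid, zyg))
            fam += 1
    for _ in range(config.n_unrelated):
        fid = f"F{fam:05d}"
        rows.append((f"{fid}_1", fid, "singleton"))
        fam += 1
    df = pd.DataFrame(rows, columns=["sample_id", "family_id", "zygosity"])
    df = df.set_index("sample_id")
    n = len(df)
    df["sex"] = np.where(rng.random(n) < config.male_fraction, "M", "F")
    # co-twins share sex and age
    fam_codes = df.groupby("family_id", sort=False).ngroup().values
    first = pd.Series(np.arange(n)).groupby(fam_codes).transform("first").values
    df["sex"] = df["sex"].values[first]
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, None)
    df["age"] = np.round(age[first], 1)
    df["bmi"] = np.round(
        np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15, None), 1)
    shape = config.depth_dispersion
    depth = rng.negative_binomial(shape, shape / (shape + config.mean_depth), n)
    df["seq_depth"] = np.maximum(depth, 1)
    df["shipment_batch"] = np.array(
        [f"ship{b}" for b in rng.integers(config.n_shipment_batches, size=n)])
    df["technician"] = np.array(
        [f"tech{b}" for b in rng.integers(config.n_technicians, size=n)])
    df["abo_typed"] = "missing"
    df["abo_inferred"] = "missing"
    df["secretor"] = "unknown"
    return df


# ---------------------------------------------------------------------------
# genotypes

def _population_haplotypes(n_hap: int, config: SimConfig,
                           table: HaplotypeTable, subpop: np.ndarray,
                           bg_freqs: np.ndarray,
                           rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_hap`` population haplotypes; returns (hap matrix, ABO label)."""
    labels = list(config.abo_allele_freqs)
    probs = np.array([config.abo_allele_freqs[a] for a in labels])
    abo_idx = rng.choice(len(labels), size=n_hap, p=probs)
    abo_labels = np.array(labels, dtype=object)[abo_idx]
    pat = {a: np.array(list(table.pattern_for(a)), dtype=int)
           for a in labels}
    n_snps = len(ABO_TAG_SNPS) + 2 + config.n_background_snps
    hap = np.zeros((n_hap, n_snps), dtype=np.int8)
    for i, a in enumerate(abo_labels):
        hap[i, :3] = pat[a]
    hap[:, 3] = rng.random(n_hap) < config.nonsecretor_allele_freq
    hap[:, 4] = rng.random(n_hap) < config.lct_allele_freq
    if config.n_background_snps:
        f = bg_freqs[subpop]  # (n_hap, n_bg)
        hap[:, 5:] = rng.random((n_hap, config.n_background_snps)) < f
    return hap, abo_labels


def generate_genotypes(cohort: pd.DataFrame,
                       config: SimConfig,
                       table: HaplotypeTable | None = None) -> PhasedGenotypes:
    """Phased genotypes for every cohort member.

    Twin families are built by simulating two parents and transmitting one
    haplotype from each: MZ co-twins receive identical transmissions, DZ
    co-twins draw independently (sharing each parental transmission with
    probability 1/2). Background SNPs can be drawn from two subpopulations
    to create ancestry structure.
    """
    config.validate()
    if table is None:
        table = default_haplotype_table()
    rng = _rng(config.seed, "genotypes")
    n_bg = config.n_background_snps
    base = rng.uniform(0.05, 0.5, size=n_bg)
    if config.subpop2_fraction > 0:
        logit = np.log(base / (1 - base))
        shift = rng.normal(0.0, config.subpop_divergence, size=(2, n_bg))
        bg_freqs = 1 / (1 + np.exp(-(logit + shift)))
    else:
        bg_freqs = np.vstack([base, base]) if n_bg else np.zeros((2, 0))

    fam_ids = cohort["family_id"].values
    zyg = cohort["zygosity"].values
    samples = list(cohort.index)
    n = len(samples)
    families = pd.unique(fam_ids)
    fam_zyg = {f: zyg[fam_ids == f][0] for f in families}
    fam_subpop = {f: int(rng.random() < config.subpop2_fraction)
                  for f in families}

    # population haplotypes: 4 per twin family (two parents), 2 per singleton
    twin_fams = [f for f in families if fam_zyg[f] in ("MZ", "DZ")]
    single_fams = [f for f in families if fam_zyg[f] == "singleton"]
    n_pool = 4 * len(twin_fams) + 2 * len(single_fams)
    pool_subpop = np.concatenate([
        np.repeat([fam_subpop[f] for f in twin_fams], 4).astype(int)
        if twin_fams else np.zeros(0, int),
        np.repeat([fam_subpop[f] for f in single_fams], 2).astype(int)
        if single_fams else np.zeros(0, int),
    ])
    pool, pool_abo = _population_haplotypes(
        n_pool, config, table, pool_subpop, bg_freqs, rng)

    n_snps = pool.shape[1]
    hap = np.zeros((n, n_snps, 2), dtype=np.int8)
    true_abo = np.empty((n, 2), dtype=object)
    sample_pos = {s: i for i, s in enumerate(samples)}

    cursor = 0
    for f in twin_fams:
        parents = pool[cursor:cursor + 4]       # p1: 0,1  p2: 2,3
        parent_abo = pool_abo[cursor:cursor + 4]
        cursor += 4
        members = [s for s, ff in zip(samples, fam_ids) if ff == f]
        if fam_zyg[f] == "MZ":
            c1 = rng.integers(2)
            c2 = rng.integers(2)
            choices = [(c1, c2), (c1, c2)]
        else:
            choices = [(rng.integers(2), rng.integers(2)) for _ in members]
        for s, (c1, c2) in zip(members, choices):
            i = sample_pos[s]
            hap[i, :, 0] = parents[c1]
            hap[i, :, 1] = parents[2 + c2]
            true_abo[i, 0] = parent_abo[c1]
            true_abo[i, 1] = parent_abo[2 + c2]
    for f in single_fams:
        s = [ss for ss, ff in zip(samples, fam_ids) if ff == f][0]
        i = sample_pos[s]
        hap[i, :, 0] = pool[cursor]
        hap[i, :, 1] = pool[cursor + 1]
        true_abo[i, 0] = pool_abo[cursor]
        true_abo[i, 1] = pool_abo[cursor + 1]
        cursor += 2

    snp_ids = np.array(list(ABO_TAG_SNPS) + [SECRETOR_SNP, LCT_SNP]
                       + [f"bg_{j:05d}" for j in range(n_bg)])
    chrom = np.array(["9", "9", "9", "19", "2"] + ["1"] * n_bg)
    pos = np.array([136153875, 136212066, 136545940, 49206674, 136407479]
                   + list(10_000 + 5_000 * np.arange(n_bg)))
    ref = np.array(["G", "G", "G", "G", "G"] + ["A"] * n_bg)
    alt = np.array(["A", "T", "C", "A", "G"] + ["C"] * n_bg)
    return PhasedGenotypes(samples, snp_ids, chrom, pos, ref, alt, hap,
                           true_abo)


def true_phenotypes(geno: PhasedGenotypes) -> pd.DataFrame:
    """Simulated-truth ABO and secretor phenotypes per sample."""
    if geno.true_abo is None:
        raise ValueError("genotypes carry no simulated ABO truth")
    abo = [abo_phenotype(a1, a2) for a1, a2 in geno.true_abo]
    sec = [call_secretor(g) for g in geno.allele_pairs(SECRETOR_SNP)]
    return pd.DataFrame({"abo_true": abo, "secretor_true": sec},
                        index=geno.samples)


# ---------------------------------------------------------------------------
# tree + taxonomy

def generate_tree(n_otus: int, seed: int) -> TreeNode:
    """Random rooted bifurcating tree over OTU leaves.

    Built by coalescent-style random pairwise joins with exponential branch
    length increments; all branch lengths are positive.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs for a tree")
    rng = np.random.default_rng([_STAGE["tree"], seed])
    nodes = [TreeNode(name=f"OTU_{i:05d}", length=None)
             for i in range(n_otus)]
    heights = [0.0] * n_otus
    while len(nodes) > 1:
        k = len(nodes)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        h = max(heights[i], heights[j]) + rng.exponential(1.0 / k) + 1e-3
        a, b = nodes[i], nodes[j]
        a.length = h - heights[i]
        b.length = h - heights[j]
        parent = TreeNode(children=[a, b])
        nodes = [nodes[x] for x in range(k) if x not in (i, j)] + [parent]
        heights = [heights[x] for x in range(k) if x not in (i, j)] + [h]
    root = nodes[0]
    root.length = None
    return root


def _clade_partition(tree: TreeNode, n_groups: int) -> dict[str, int]:
    """Partition leaves into ``n_groups`` clades by repeatedly splitting the
    shallowest splittable clade root."""
    frontier = [tree]
    depth = {id(tree): 0.0}
    while len(frontier) < n_groups:
        internal = [nd for nd in frontier if nd.children]
        if not internal:
            break
        nxt = min(internal, key=lambda nd: (depth[id(nd)], nd.name or ""))
        frontier.remove(nxt)
        for child in nxt.children:
            depth[id(child)] = depth[id(nxt)] + (child.length or 0.0)
            frontier.append(child)
    out = {}
    for g, nd in enumerate(frontier):
        if nd.children:
            for leaf in nd.tips():
                out[leaf.name] = g
        else:
            out[nd.name] = g
    return out


def assign_taxonomy(tree: TreeNode, config: SimConfig) -> pd.Series:
    """Greengenes-style lineage strings from nested tree clades.

    Rank group counts scale with the number of OTUs; a configurable fraction
    of OTUs is left unassigned at the genus rank to exercise
    'unclassified-<parent>' handling downstream.
    """
    leaves = [t.name for t in tree.tips()]
    n = len(leaves)
    targets = {
        "phylum": max(2, n // 25),
        "class": max(3, n // 16),
        "order": max(4, n // 12),
        "family": max(5, n // 8),
        "genus": max(6, n // 5),
    }
    prev = 1
    parts = {}
    for rank in RANKS:
        targets[rank] = max(targets[rank], prev)
        parts[rank] = _clade_partition(tree, targets[rank])
        prev = targets[rank]
    rng = np.random.default_rng([_STAGE["tree"], config.seed, 7])
    unassigned = rng.random(n) < config.unassigned_genus_fraction
    prefix = {"phylum": "p", "class": "c", "order": "o",
              "family": "f", "genus": "g"}
    lineages = {}
    for i, leaf in enumerate(leaves):
        fields = ["k__Bacteria"]
        for rank in RANKS:
            g = parts[rank][leaf]
            if rank == "genus" and unassigned[i]:
                fields.append("g__")
            else:
                fields.append(f"{prefix[rank]}__{prefix[rank].upper()}{g:03d}")
        lineages[leaf] = ";".join(fields)
    return pd.Series(lineages)


# ---------------------------------------------------------------------------
# OTU counts

def generate_otu_counts(cohort: pd.DataFrame, geno: PhasedGenotypes,
                        tree: TreeNode, config: SimConfig) -> OtuTable:
    """Multinomial OTU counts from Gaussian latent log-abundances.

    Latent value per (sample, OTU) = OTU baseline + family effect (shared
    within family) + additive genetic effect (correlation 1 within MZ pairs,
    0.5 within DZ pairs via mid-parent values) + technical covariate effects
    + injected phenotype effects + residual noise. Each sample's counts are
    one multinomial draw of its sequencing depth over softmax(latent).
    """
    config.validate()
    leaves = [t.name for t in tree.tips()]
    if len(leaves) != config.n_otus:
        raise ValueError("tree leaf count != config.n_otus")
    if list(cohort.index) != list(geno.samples):
        raise ValueError("cohort and genotype sample IDs differ")
    rng = _rng(config.seed, "otu")
    n, m = len(cohort), config.n_otus

    baseline = rng.normal(0.0, config.baseline_sd, size=m)
    latent = np.tile(baseline, (n, 1))

    fam_codes = cohort.groupby("family_id", sort=False).ngroup().values
    n_fam = fam_codes.max() + 1
    latent += rng.normal(0.0, config.family_sd, size=(n_fam, m))[fam_codes]

    # additive genetic: mid-parent + Mendelian-segregation residual
    parent_mean = rng.normal(0.0, config.additive_sd / np.sqrt(2.0),
                             size=(n_fam, m))
    seg = rng.normal(0.0, config.additive_sd * np.sqrt(0.5), size=(n, m))
    zyg = cohort["zygosity"].values
    is_twin = np.isin(zyg, ["MZ", "DZ"])
    # MZ co-twins share the segregation draw: copy first member's row
    first = pd.Series(np.arange(n)).groupby(fam_codes).transform("first").values
    mz = zyg == "MZ"
    seg[mz] = seg[first[mz]]
    additive = np.where(is_twin[:, None], parent_mean[fam_codes] + seg,
                        rng.normal(0.0, config.additive_sd, size=(n, m)))
    latent += additive

    ce = config.covariate_effects
    def z(v):
        v = np.asarray(v, dtype=float)
        s = v.std()
        return (v - v.mean()) / s if s > 0 else v * 0.0
    if ce.get("age", 0.0):
        latent += np.outer(z(cohort["age"]), rng.normal(0, 1, m)) * ce["age"]
    if ce.get("sex", 0.0):
        latent += np.outer(z(cohort["sex"] == "M"),
                           rng.normal(0, 1, m)) * ce["sex"]
    if ce.get("depth", 0.0):
        latent += np.outer(z(np.log(cohort["seq_depth"])),
                           rng.normal(0, 1, m)) * ce["depth"]
    if ce.get("batch", 0.0):
        for col in ("shipment_batch", "technician"):
            codes = pd.factorize(cohort[col])[0]
            offs = rng.normal(0.0, ce["batch"],
                              size=(codes.max() + 1, m))
            latent += offs[codes]

    if config.effect_spec:
        truth = true_phenotypes(geno)
        for spec in config.effect_spec:
            pheno = (truth["abo_true"] if spec.phenotype == "abo"
                     else truth["secretor_true"])
            mask = (pheno.values == spec.level)
            latent[mask, spec.taxon] += spec.size * config.residual_sd

    latent += rng.normal(0.0, config.residual_sd, size=(n, m))

    logits = latent - latent.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    depths = cohort["seq_depth"].values.astype(int)
    counts = np.vstack([rng.multinomial(depths[i], probs[i])
                        for i in range(n)])
    df = pd.DataFrame(counts, index=cohort.index, columns=leaves)
    return OtuTable(df, assign_taxonomy(tree, config))


# ---------------------------------------------------------------------------
# full bundle

@dataclass
class SimulatedCohort:
    cohort: pd.DataFrame
    genotypes: PhasedGenotypes
    tree: TreeNode
    otu_table: OtuTable
    truth: pd.DataFrame
    config: SimConfig


def simulate_cohort(config: SimConfig,
                    table: HaplotypeTable | None = None) -> SimulatedCohort:
    """Run every generator stage and attach observed phenotypes.

    ``abo_typed`` is set for a configured fraction of samples and equals the
    simulated truth except for a configured serotyping error rate; the
    ``secretor`` column is the truth with a configured fraction masked as
    unknown (assay failures).
    """
    cohort = generate_cohort(config)
    geno = generate_genotypes(cohort, config, table)
    tree = generate_tree(config.n_otus, config.seed)
    otus = generate_otu_counts(cohort, geno, tree, config)
    truth = true_phenotypes(geno)

    rng = _rng(config.seed, "phenotyping")
    n = len(cohort)
    typed = rng.random(n) < config.typed_fraction
    abo_typed = np.where(typed, truth["abo_true"].values, "missing")
    err = typed & (rng.random(n) < config.typing_error_rate)
    classes = np.array(["A", "AB", "B", "O"], dtype=object)
    for i in np.flatnonzero(err):
        others = classes[classes != abo_typed[i]]
        abo_typed[i] = rng.choice(others)
    cohort["abo_typed"] = abo_typed
    unknown = rng.random(n) < config.secretor_unknown_fraction
    cohort["secretor"] = np.where(unknown, "unknown",
                                  truth["secretor_true"].values)
    cohort["secretor_unknown"] = unknown
    return SimulatedCohort(cohort, geno, tree, otus, truth, config)
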