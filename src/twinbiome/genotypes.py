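"""ABO and secretor phenotype inference from phased tag-SNP genotypes, plus
genotype QC (MAF / Hardy-Weinberg filters), LD pruning, and ancestry PCA.

ABO alleles (A1, A2, B, O) are read off each phased haplotype by exact lookup
in a three-SNP tag table; the diploid phenotype follows classical dominance
(A and B dominant over O, A+B codominant). Secretor status is carried by
rs601338 in FUT2: homozygotes for the nonsense (A) allele are non-secretors.

The default tag table is a reconstruction: the B allele is tagged by the
minor allele of rs8176746, A1 by the minor allele of rs651007 (a close proxy
of rs507666), A2 by the minor allele of rs8176704, and the all-reference
pattern is O. Any other pattern is unresolved and the sample is excluded
from phenotype-based analyses. The table is a plain TSV and fully
user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, exp
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ABO_TAG_SNPS

ABO_ALLELES = ("A1", "A2", "B", "O")
UNRESOLVED = "unresolved"


# ---------------------------------------------------------------------------
# haplotype table

@dataclass(frozen=True)
class HaplotypeTable:
    """Lookup from phased allele patterns (strings over '0'/'1', ref/alt in
    ``snp_ids`` order) to ABO allele labels."""

    snp_ids: tuple[str, ...]
    patterns: dict[str, str]  # pattern -> allele label

    def __post_init__(self) -> None:
        for pat in self.patterns:
            if len(pat) != len(self.snp_ids):
                raise ValueError(
                    f"pattern {pat!r} length != {len(self.snp_ids)} SNPs")
        labels = set(self.patterns.values())
        missing = set(ABO_ALLELES) - labels
        if missing:
            raise ValueError(f"haplotype table lacks alleles: {sorted(missing)}")

    def pattern_for(self, allele: str) -> str:
        """First pattern mapping to ``allele`` (used by the simulator)."""
        for pat, lab in self.patterns.items():
            if lab == allele:
                return pat
        raise KeyError(allele)

    def write_tsv(self, path: str | Path) -> None:
        rows = [dict(zip(self.snp_ids, pat), allele=lab)
                for pat, lab in self.patterns.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        snp_ids = tuple(c for c in df.columns if c != "allele")
        patterns = {"".join(row[s] for s in snp_ids): row["allele"]
                    for _, row in df.iterrows()}
        return cls(snp_ids, patterns)


def default_haplotype_table() -> HaplotypeTable:
    return HaplotypeTable(
        snp_ids=tuple(ABO_TAG_SNPS),  # rs651007, rs8176746, rs8176704
        patterns={
            "000": "O",
            "100": "A1",
            "001": "A2",
            "010": "B",
        },
    )


# ---------------------------------------------------------------------------
# phased genotype container

@dataclass
class PhasedGenotypes:
    """Per-individual haplotype pairs over named SNPs.

    ``haplotypes`` has shape (n_samples, n_snps, 2) with entries 0 (ref) or
    1 (alt). ``true_abo`` optionally records the simulated ABO allele label
    of each haplotype for round-trip testing.
    """

    samples: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    true_abo: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, s, two = self.haplotypes.shape
        if two != 2 or n != len(self.samples) or s != len(self.snp_ids):
            raise ValueError("haplotype array shape inconsistent with labels")
        self._index = {sid: i for i, sid in enumerate(self.snp_ids)}

    def snp_index(self, snp_id: str) -> int:
        return self._index[snp_id]

    def dosage(self, snp_ids=None) -> pd.DataFrame:
        """Alt-allele dosage matrix (samples x SNPs)."""
        if snp_ids is None:
            snp_ids = list(self.snp_ids)
        idx = [self.snp_index(s) for s in snp_ids]
        return pd.DataFrame(self.haplotypes[:, idx, :].sum(axis=2),
                            index=self.samples, columns=list(snp_ids))

    def haplotype_patterns(self, snp_ids) -> np.ndarray:
        """(n, 2) array of '0'/'1' pattern strings over ``snp_ids``."""
        idx = [self.snp_index(s) for s in snp_ids]
        sub = self.haplotypes[:, idx, :]
        n = sub.shape[0]
        out = np.empty((n, 2), dtype=object)
        for h in (0, 1):
            cols = sub[:, :, h].astype("U1")
            out[:, h] = np.array(["".join(row) for row in cols], dtype=object)
        return out

    def allele_pairs(self, snp_id: str) -> list[str]:
        """Unordered base-pair strings (e.g. 'GA') at one SNP."""
        j = self.snp_index(snp_id)
        bases = np.array([self.ref[j], self.alt[j]])
        return ["".join(bases[self.haplotypes[i, j, :]])
                for i in range(len(self.samples))]

    def background_mask(self) -> np.ndarray:
        return np.char.startswith(self.snp_ids.astype(str), "bg_")


# ---------------------------------------------------------------------------
# phenotype calling

def call_abo_alleles(haplotype: str, table: HaplotypeTable) -> str:
    """Exact lookup of one phased allele pattern; unmatched -> 'unresolved'."""
    if len(haplotype) != len(table.snp_ids):
        raise ValueError(
            f"pattern length {len(haplotype)} != {len(table.snp_ids)} SNPs")
    return table.patterns.get(haplotype, UNRESOLVED)


def abo_phenotype(a1: str, a2: str) -> str:
    """Diploid ABO phenotype from two allele labels (symmetric)."""
    for a in (a1, a2):
        if a not in ABO_ALLELES:
            raise ValueError(f"unresolved or unknown ABO allele {a!r}")
    has_a = any(a in ("A1", "A2") for a in (a1, a2))
    has_b = "B" in (a1, a2)
    if has_a and has_b:
        return "AB"
    if has_a:
        return "A"
    if has_b:
        return "B"
    return "O"


def call_secretor(genotype: str | None) -> str:
    """Secretor status from the rs601338 base pair ('GA', 'AA', ...).

    Homozygosity for the nonsense A allele gives the non-secretor phenotype;
    any G allele secretes. ``None`` or empty -> 'unknown'.
    """
    if genotype is None or genotype == "" or genotype == "..":
        return "unknown"
    alleles = set(genotype)
    if not alleles <= {"G", "A"}:
        raise ValueError(f"unexpected rs601338 alleles {genotype!r}")
    return "NS" if genotype == "AA" else "S"


def infer_phenotypes(cohort: pd.DataFrame, geno: PhasedGenotypes,
                     table: HaplotypeTable | None = None) -> pd.DataFrame:
    """Fill ``abo_inferred`` and ``secretor`` columns of a cohort table.

    Samples with any unresolved ABO haplotype get ``abo_inferred='missing'``
    (the haplotype-match retention rule). Returns a copy, row-aligned with
    ``cohort``.
    """
    if table is None:
        table = default_haplotype_table()
    out = cohort.copy()
    order = [out.index.get_loc(s) if s in out.index else None
             for s in geno.samples]
    pats = geno.haplotype_patterns(table.snp_ids)
    abo = []
    for h1, h2 in pats:
        a1 = call_abo_alleles(h1, table)
        a2 = call_abo_alleles(h2, table)
        abo.append("missing" if UNRESOLVED in (a1, a2)
                   else abo_phenotype(a1, a2))
    sec = [call_secretor(g) for g in geno.allele_pairs("rs601338")]
    abo_s = pd.Series(abo, index=geno.samples)
    sec_s = pd.Series(sec, index=geno.samples)
    out["abo_inferred"] = abo_s.reindex(out.index).fillna("missing")
    out["secretor"] = sec_s.reindex(out.index).fillna("unknown")
    # keep recorded unknowns unknown (e.g. failed secretor assay)
    if "secretor_unknown" in out.columns:
        out.loc[out["secretor_unknown"].astype(bool), "secretor"] = "unknown"
    return out


def resolve_abo(cohort: pd.DataFrame) -> pd.Series:
    """Analysis ABO phenotype: genotype-inferred where available (it wins on
    typed/inferred discordance), 'missing' otherwise."""
    abo = cohort["abo_inferred"].copy()
    if "abo_typed" in cohort.columns:
        fallback = (abo == "missing") & (cohort["abo_typed"] != "missing")
        abo[fallback] = cohort.loc[fallback, "abo_typed"]
    return abo


def concordance(typed: pd.Series, inferred: pd.Series) -> float:
    """Fraction of samples on which two call sets agree, over samples where
    both are non-missing."""
    typed, inferred = typed.align(inferred, join="inner")
    ok = (typed != "missing") & (inferred != "missing")
    if ok.sum() == 0:
        raise ValueError("no samples with both typed and inferred calls")
    return float((typed[ok] == inferred[ok]).mean())


# ---------------------------------------------------------------------------
# variant QC

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test: total probability of heterozygote
    counts no more likely than the observed one, conditional on allele
    counts."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_alt = min(n_alt, 2 * n - n_alt)  # work with the minor allele
    if n == 0 or n_alt == 0:
        return 1.0

    def log_prob(het: int) -> float:
        hom_alt = (n_alt - het) // 2
        hom_ref = n - het - hom_alt
        return (lgamma(n + 1) - lgamma(hom_ref + 1) - lgamma(het + 1)
                - lgamma(hom_alt + 1) + het * np.log(2)
                + lgamma(n_alt + 1) + lgamma(2 * n - n_alt + 1)
                - lgamma(2 * n + 1))

    hets = np.arange(n_alt % 2, n_alt + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs_het = n_het if n_het <= n_alt else n_alt  # guard, should not trigger
    p_obs = probs[np.searchsorted(hets, obs_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def filter_variants(dosage: pd.DataFrame, maf_min: float = 0.05,
                    hwe_p_min: float = 0.001) -> list[str]:
    """SNP IDs passing minor-allele-frequency and exact HWE filters.

    Monomorphic SNPs have MAF 0 and are removed, not errors.
    """
    keep = []
    g = dosage.values
    for j, snp in enumerate(dosage.columns):
        col = g[:, j]
        p = col.mean() / 2.0
        maf = min(p, 1 - p)
        if maf < maf_min:
            continue
        counts = np.bincount(col.astype(int), minlength=3)
        if hwe_exact_p(int(counts[0]), int(counts[1]), int(counts[2])) < hwe_p_min:
            continue
        keep.append(snp)
    return keep


# ---------------------------------------------------------------------------
# LD pruning

def _r2(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_prune(dosage: pd.DataFrame, positions: np.ndarray,
             window_kb: float = 1000.0, step_snps: int = 50,
             r2_max: float = 0.2) -> list[str]:
    """Greedy windowed LD pruning of position-sorted SNPs.

    Within each window (SNPs from the window start to the last SNP within
    ``window_kb`` kilobases), violating pairs are scanned in index order;
    of the first pair with genotype r^2 > ``r2_max`` the member with lower
    MAF is removed (on a tie, the higher index), and the scan restarts.
    The window start then advances by ``step_snps``.
    """
    positions = np.asarray(positions, dtype=float)
    if np.any(np.diff(positions) < 0):
        raise ValueError("SNP positions must be sorted")
    g = dosage.values.astype(float)
    m = g.shape[1]
    p = g.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    retained = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        end = int(np.searchsorted(positions,
                                  positions[start] + window_kb * 1000.0,
                                  side="right"))
        changed = True
        while changed:
            changed = False
            idx = [i for i in range(start, end) if retained[i]]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    i, j = idx[a], idx[b]
                    if _r2(g[:, i], g[:, j]) > r2_max:
                        drop = i if (maf[i] < maf[j]) else j
                        retained[drop] = False
                        changed = True
                        break
                if changed:
                    break
        start += step_snps
    return [dosage.columns[i] for i in range(m) if retained[i]]


# ---------------------------------------------------------------------------
# ancestry PCA

@dataclass
class AncestryPCs:
    coords: pd.DataFrame          # samples x PC1..PCk
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        vf = self.variance_fraction
        if np.any(vf < -1e-12) or np.any(vf > 1 + 1e-12):
            raise ValueError("variance fractions outside [0, 1]")
        if np.any(np.diff(vf) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")


def ancestry_pca(dosage: pd.DataFrame, k: int = 5) -> AncestryPCs:
    """PCA of genotypes standardized the smartpca way: each SNP centered at
    2p and scaled by sqrt(2p(1-p)); monomorphic SNPs are dropped."""
    g = dosage.values.astype(float)
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    g = g[:, poly]
    p = p[poly]
    x = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the genotype matrix")
    scores = u[:, :k] * s[:k]
    frac = (s[:k] ** 2) / (s ** 2).sum()
    coords = pd.DataFrame(scores, index=dosage.index,
                          columns=[f"PC{i+1}" for i in range(k)])
    return AncestryPCs(coords, frac)
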