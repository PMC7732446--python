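"""Synthetic inbred-line SNP panels with known subpopulation structure.

The generator follows the Balding-Nichols model: per locus an ancestral
allele frequency p is drawn uniformly from the configured MAF range
(reflected into (0,1) with probability 1/2 so either allele can be the
common one), and each subpopulation k draws its own frequency

    p_k ~ Beta( p (1-F)/F,  (1-p) (1-F)/F ),

where F is the fixation index (FST) controlling between-population
differentiation; at F = 0 the limit p_k = p is used exactly. Every line is
fully homozygous (the selfing limit of an inbred panel): it draws a single
allele per locus with probability p_k. The two alleles of a locus are two
distinct nucleotides sampled without replacement from {A, C, G, T}, so all
four letters are exercised across loci.

Defaults emulate a two-subpopulation maize panel of 97 + 86 inbred lines
genotyped at 4,812 loci with MAF > 0.15 and no missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import MISSING, NUCLEOTIDES, SNPMatrix

__all__ = ["SimulationConfig", "simulate_panel", "empirical_fst"]


@dataclass
class SimulationConfig:
    """Parameters of the panel generator (see module docstring).

    ``fst`` in [0, 1); ``ancestral_maf_range`` within (0, 0.5];
    ``missing_rate`` is a uniform per-call missingness fraction (default 0,
    matching the no-missing-data filter of the study design).
    """

    n_subpops: int = 2
    lines_per_subpop: Sequence[int] = (97, 86)
    n_loci: int = 4812
    fst: float = 0.3
    ancestral_maf_range: tuple = (0.15, 0.5)
    missing_rate: float = 0.0
    seed: int = 0
    subpop_names: Sequence[str] = None

    def __post_init__(self):
        self.lines_per_subpop = list(self.lines_per_subpop)
        if self.n_subpops < 1 or len(self.lines_per_subpop) != self.n_subpops:
            raise ValueError("lines_per_subpop length must equal n_subpops (>= 1)")
        if any(l < 1 for l in self.lines_per_subpop) or self.n_loci < 1:
            raise ValueError("need at least one line per subpopulation and one locus")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.subpop_names is None:
            self.subpop_names = [f"pop{k + 1}" for k in range(self.n_subpops)]
        self.subpop_names = list(self.subpop_names)
        if len(self.subpop_names) != self.n_subpops:
            raise ValueError("subpop_names length must equal n_subpops")


def simulate_panel(cfg: SimulationConfig) -> SNPMatrix:
    """Draw a fully homozygous panel with true subpopulation labels."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    lo, hi = cfg.ancestral_maf_range
    p = rng.uniform(lo, hi, size=L)
    flip = rng.random(L) < 0.5  # either allele may be the common one
    p = np.where(flip, 1.0 - p, p)

    if cfg.fst == 0.0:
        pk = np.tile(p, (cfg.n_subpops, 1))
    else:
        c = (1.0 - cfg.fst) / cfg.fst
        pk = rng.beta(p * c, (1.0 - p) * c, size=(cfg.n_subpops, L))

    # two distinct nucleotides per locus
    allele_pairs = np.stack([
        rng.choice(len(NUCLEOTIDES), size=2, replace=False) for _ in range(L)
    ])
    letters = np.array(NUCLEOTIDES, dtype="<U1")
    a0 = letters[allele_pairs[:, 0]]  # allele drawn with prob p_k
    a1 = letters[allele_pairs[:, 1]]

    rows, labels, sample_ids = [], [], []
    for k, (n_k, name) in enumerate(zip(cfg.lines_per_subpop, cfg.subpop_names)):
        draws = rng.random((n_k, L)) < pk[k]
        rows.append(np.where(draws, a0[None, :], a1[None, :]))
        labels.extend([name] * n_k)
        sample_ids.extend(f"{name}_L{i + 1:03d}" for i in range(n_k))
    calls = np.concatenate(rows, axis=0)

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, MISSING, calls)

    locus_ids = [f"S{j + 1}" for j in range(L)]
    return SNPMatrix(sample_ids, locus_ids, calls, true_labels=labels)


def empirical_fst(m: SNPMatrix, labels: Sequence) -> float:
    """Hudson-style FST estimate averaged over loci (ratio of averages).

    For each subpopulation pair and locus with sample frequencies p1, p2 on
    n1, n2 haploid lines:

        num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)

    and FST = mean(num) / mean(den) over loci, averaged over pairs.
    """
    labels = np.asarray(labels)
    pops = np.unique(labels)
    if len(pops) < 2:
        raise ValueError("need at least 2 subpopulations")
    if any((labels == g).sum() < 2 for g in pops):
        raise ValueError("need at least 2 lines per subpopulation")

    for j in range(m.n_loci):
        col = m.calls[:, j]
        alleles = np.unique(col[col != MISSING])
        if len(alleles) > 2:
            raise ValueError(f"locus {m.locus_ids[j]} has more than two alleles")
    # reference allele per locus: lexicographically first observed
    calls = m.calls
    obs_mask = calls != MISSING
    ref_alleles = np.array([
        sorted(np.unique(calls[obs_mask[:, j], j]))[0] if obs_mask[:, j].any() else "A"
        for j in range(m.n_loci)
    ], dtype="<U1")

    est = []
    for i in range(len(pops)):
        for k in range(i + 1, len(pops)):
            rows1 = labels == pops[i]
            rows2 = labels == pops[k]
            with np.errstate(invalid="ignore"):
                n1 = obs_mask[rows1].sum(axis=0).astype(float)
                n2 = obs_mask[rows2].sum(axis=0).astype(float)
                p1 = ((calls[rows1] == ref_alleles) & obs_mask[rows1]).sum(axis=0) / n1
                p2 = ((calls[rows2] == ref_alleles) & obs_mask[rows2]).sum(axis=0) / n2
            ok = (n1 > 1) & (n2 > 1)
            p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            keep = den > 0
            if not keep.any():
                raise ValueError("monomorphic panel: FST undefined")
            est.append(num[keep].mean() / den[keep].mean())
    return float(np.clip(np.mean(est), 0.0, 1.0))
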