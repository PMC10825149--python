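"""Synthetic ground-truth landscapes and UMI-barcoded competition sequencing.

This module generates everything the downstream pipeline consumes, with the
statistical structure the analysis assumes:

* five-environment fitness landscapes built from per-site receptor effects
  (most mutations deleterious on LamB, OmpF effects spread around zero),
  sparse pairwise epistasis, negative epistasis between opposing
  specialist mutations (hybrid incompatibility), and environment mixing
  along the receptor-competition spectrum;
* a combinatorial library at near-uniform genotype frequencies;
* pre/post-competition samples of ~1e6 unique molecular barcodes (UMIs),
  each observed by several reads carrying independent per-base
  substitution errors.

Reads exist in two interchangeable representations: full FASTQ records
(UMI appended to the read name as ``UMI:<seq>``) for format-level testing,
and a compact array form (:class:`ReadArrays`) holding per-read site-allele
codes plus a sparse list of off-site error events, which scales to millions
of UMIs.  Both carry exactly the same information about the programmed
sites and off-target substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    ENVIRONMENTS,
    N_GENOTYPES,
    N_SITES,
    FitnessLandscape,
    MutationSite,
    ValidationError,
    genotype_bit_matrix,
    validate_sites,
)

# Synthetic reference amplicon (300 nt) standing in for the sequenced J
# fragment, and the default mutation-site metadata on it.  Sites 2/3 and
# 7/8 are placed within one codon each, mirroring the library design where
# those site pairs alter the same codon.
REFERENCE_AMPLICON = (
    "AGTCCAATATCCGCCGATCTCCGGCAGGCCACGGTCCATCCAAGCTTCACATAATACGCC"
    "CGCCTTAGGTGTGGTGCTGTAGCGACTACGGTGCCTGTAAAGAGGTGCCATTTAACCTCA"
    "TTCTTGCCCGAGATGCCCGACTGTCTATCCGAAAGCGAATCTTGGAGATAGCACGTCTGA"
    "TTACTTGCCTGAGTTAGCCGAAGCCCGTGTCGTAGACATTTATAAGCACCGCTGAGATCC"
    "ATTCCGTGTGGCTAAGGTAAGTCGTAGCCCCCGGACTGTTCCGGGTGAAAGGCAAATATT"
)

DEFAULT_SITES: tuple[MutationSite, ...] = validate_sites(
    [
        MutationSite(1, 30, "C", "T", "site1"),
        MutationSite(2, 52, "T", "C", "site2 (same codon as 3)"),
        MutationSite(3, 53, "A", "G", "site3 (same codon as 2)"),
        MutationSite(4, 98, "T", "C", "site4"),
        MutationSite(5, 131, "A", "G", "site5"),
        MutationSite(6, 170, "A", "G", "site6"),
        MutationSite(7, 214, "A", "G", "site7 (same codon as 8)"),
        MutationSite(8, 216, "A", "G", "site8 (same codon as 7)"),
        MutationSite(9, 262, "T", "C", "site9"),
    ]
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_ENV_WEIGHTS: dict[str, tuple[float, float]] = {
    # (alpha, beta): S_env = alpha * S_LamB + beta * S_OmpF
    "A": (0.0, 1.0),  # OmpF-only hosts
    "B": (0.15, 0.85),  # mixed hosts, L-specialist competitor
    "C": (0.35, 0.65),  # mixed hosts, generalist competitor
    "D": (0.80, 0.20),  # mixed hosts, O-specialist competitor
    "E": (1.0, 0.0),  # LamB-only hosts
}


@dataclass
class GroundTruthModel:
    """Generative model behind the five synthetic landscapes.

    Receptor-specific genotype scores are additive with sparse pairwise
    epistasis:  ``S_L(g) = sum dL_i + sum eL_ij`` over mutated sites/pairs
    (``S_O`` analogous).  Environment landscapes mix the two receptor
    scores, ``S_env = alpha * S_L + beta * S_O`` (+ sparse environment-
    specific pairwise perturbations), with alpha the LamB share of the
    selective pressure.  Incompatibility pairs couple an L-adaptive site to
    an O-adaptive site with negative epistasis on both receptors, so that
    hybrids of opposing specialists are penalised everywhere.
    """

    d_lamb: np.ndarray
    d_ompf: np.ndarray
    e_lamb: dict[tuple[int, int], float] = field(default_factory=dict)
    e_ompf: dict[tuple[int, int], float] = field(default_factory=dict)
    incompatibility_pairs: tuple[tuple[int, int], ...] = ()
    env_weights: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENV_WEIGHTS)
    )
    env_perturbations: dict[str, dict[tuple[int, int], float]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.d_lamb = np.asarray(self.d_lamb, dtype=float)
        self.d_ompf = np.asarray(self.d_ompf, dtype=float)
        if self.d_lamb.shape != (N_SITES,) or self.d_ompf.shape != (N_SITES,):
            raise ValidationError("per-site effects must have length 9")
        self.validate_weights()

    def validate_weights(self) -> None:
        for env, (alpha, beta) in self.env_weights.items():
            if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-9:
                raise ValidationError(
                    f"environment {env}: weights must be non-negative and sum to 1"
                )
        if self.env_weights["A"] != (0.0, 1.0) or self.env_weights["E"] != (1.0, 0.0):
            raise ValidationError("environment A must be pure OmpF, E pure LamB")
        alphas = [self.env_weights[e][0] for e in ("B", "C", "D")]
        if not (0 < alphas[0] < alphas[1] < alphas[2] < 1):
            raise ValidationError("need 0 < alpha_B < alpha_C < alpha_D < 1")

    @classmethod
    def default(
        cls,
        seed: int = 0,
        lamb_effect_mean: float = -0.5,
        lamb_effect_sd: float = 0.3,
        ompf_effect_sd: float = 0.6,
        epistasis_prob: float = 0.2,
        epistasis_sd: float = 0.3,
        incompatibility_effect: float = -0.8,
        n_incompatibility_per_side: int = 2,
        env_perturbation_prob: float = 0.1,
        env_perturbation_sd: float = 0.2,
        l_adaptive_lamb_mean: float = 0.25,
        l_adaptive_lamb_sd: float = 0.1,
        l_adaptive_ompf_shift: float = -0.8,
        o_adaptive_ompf_shift: float = 0.6,
        tradeoff_strength: float = 1.0,
    ) -> "GroundTruthModel":
        """Draw a model with the default effect distributions.

        Per-site receptor effects are median-centred after drawing (LamB to
        median ``lamb_effect_mean``, OmpF to median 0), so any seed produces
        the asymmetric-pleiotropy pattern the generator is meant to emulate:
        the typical mutation is deleterious on the native receptor LamB
        while OmpF effects are evenly spread about zero.

        Two designated L-adaptive sites carry an explicit specialization
        trade-off (near-neutral to mildly beneficial on LamB, strongly
        deleterious on OmpF), guaranteeing that the library contains both
        LamB- and OmpF-specialist peaks; the two sites with the largest
        OmpF benefit are designated O-adaptive, and every L-adaptive x
        O-adaptive pair carries the incompatibility epistasis.
        """
        rng = np.random.default_rng(seed)
        raw_o = rng.normal(0.0, ompf_effect_sd, N_SITES)
        o_order = np.argsort(raw_o)
        k = n_incompatibility_per_side
        l_adaptive = (o_order[:k] + 1).tolist()  # most OmpF-deleterious draws
        o_adaptive = (o_order[::-1][:k] + 1).tolist()
        raw_o[o_order[:k]] += l_adaptive_ompf_shift
        raw_o[o_order[::-1][:k]] += o_adaptive_ompf_shift
        d_ompf = raw_o - np.median(raw_o)

        raw_l = rng.normal(lamb_effect_mean, lamb_effect_sd, N_SITES)
        raw_l[o_order[:k]] = rng.normal(l_adaptive_lamb_mean, l_adaptive_lamb_sd, k)
        d_lamb = raw_l - np.median(raw_l) + lamb_effect_mean
        # keep the designated sites' LamB effects as drawn (the median
        # shift applies to the deleterious bulk only)
        d_lamb[o_order[:k]] = raw_l[o_order[:k]]
        # receptor trade-off coupling: gaining fitness on the novel receptor
        # OmpF costs fitness on the native receptor LamB, so no mutation
        # yields a cheap generalist improvement
        d_lamb = d_lamb - tradeoff_strength * np.clip(d_ompf, 0.0, None)

        e_lamb: dict[tuple[int, int], float] = {}
        e_ompf: dict[tuple[int, int], float] = {}
        for i in range(1, N_SITES + 1):
            for j in range(i + 1, N_SITES + 1):
                if rng.random() < epistasis_prob:
                    e_lamb[(i, j)] = rng.normal(0.0, epistasis_sd)
                if rng.random() < epistasis_prob:
                    e_ompf[(i, j)] = rng.normal(0.0, epistasis_sd)
        pairs = []
        for i in l_adaptive:
            for j in o_adaptive:
                pair = (min(i, j), max(i, j))
                pairs.append((i, j))
                e_lamb[pair] = e_lamb.get(pair, 0.0) + incompatibility_effect
                e_ompf[pair] = e_ompf.get(pair, 0.0) + incompatibility_effect

        # Exact pleiotropy centring: a uniform shift of the per-site effects
        # shifts every (background, mutation) fitness change by the same
        # constant, so re-centre both receptors on the pair-level median --
        # LamB to the typical deleterious effect, OmpF to zero -- making the
        # emulated Fig-style pleiotropy asymmetry hold for every seed.
        probe = cls(
            d_lamb=d_lamb,
            d_ompf=d_ompf,
            e_lamb=dict(e_lamb),
            e_ompf=dict(e_ompf),
            seed=seed,
        )
        s_l, s_o = probe.receptor_scores()
        deltas_l, deltas_o = [], []
        for site in range(N_SITES):
            bit = 1 << site
            backgrounds = np.array([g for g in range(N_GENOTYPES) if not g & bit])
            deltas_l.append(s_l[backgrounds | bit] - s_l[backgrounds])
            deltas_o.append(s_o[backgrounds | bit] - s_o[backgrounds])
        d_lamb = d_lamb - np.median(np.concatenate(deltas_l)) + lamb_effect_mean
        d_ompf = d_ompf - np.median(np.concatenate(deltas_o))

        env_perturbations: dict[str, dict[tuple[int, int], float]] = {}
        for env in ("B", "C", "D"):  # mixed-host environments only
            perturb: dict[tuple[int, int], float] = {}
            for i in range(1, N_SITES + 1):
                for j in range(i + 1, N_SITES + 1):
                    if rng.random() < env_perturbation_prob:
                        perturb[(i, j)] = rng.normal(0.0, env_perturbation_sd)
            env_perturbations[env] = perturb

        return cls(
            d_lamb=d_lamb,
            d_ompf=d_ompf,
            e_lamb=e_lamb,
            e_ompf=e_ompf,
            incompatibility_pairs=tuple(pairs),
            env_perturbations=env_perturbations,
            seed=seed,
        )

    def receptor_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """(S_L, S_O) arrays over all 512 genotypes (EvoC = 0 on both)."""
        bits = genotype_bit_matrix().astype(float)
        s_l = bits @ self.d_lamb
        s_o = bits @ self.d_ompf
        for (i, j), val in self.e_lamb.items():
            s_l += val * bits[:, i - 1] * bits[:, j - 1]
        for (i, j), val in self.e_ompf.items():
            s_o += val * bits[:, i - 1] * bits[:, j - 1]
        return s_l, s_o


def generate_true_landscapes(model: GroundTruthModel) -> dict[str, FitnessLandscape]:
    """Ground-truth landscapes for all five environments (no missing values)."""
    model.validate_weights()
    s_l, s_o = model.receptor_scores()
    bits = genotype_bit_matrix().astype(float)
    landscapes = {}
    for env_id, env in ENVIRONMENTS.items():
        alpha, beta = model.env_weights[env_id]
        values = alpha * s_l + beta * s_o
        for (i, j), val in model.env_perturbations.get(env_id, {}).items():
            values = values + val * bits[:, i - 1] * bits[:, j - 1]
        landscapes[env_id] = FitnessLandscape(env, values)
    return landscapes


def generate_library_frequencies(
    n_genotypes: int = N_GENOTYPES,
    concentration: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Near-uniform library genotype frequencies (Dirichlet draw).

    The default concentration of 100 per genotype gives ~10% coefficient of
    variation around 1/512, emulating the "relatively uniform" frequencies
    of the engineered lysogen libraries.
    """
    if concentration <= 0:
        raise ValidationError("concentration must be positive")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(n_genotypes, concentration))


def propagate_frequencies(f0: np.ndarray, s: np.ndarray, duration: float = 1.0) -> np.ndarray:
    """Expected post-competition frequencies: f_T(g) proportional to f0(g)*exp(S(g)*T)."""
    f0 = np.asarray(f0, dtype=float)
    if abs(f0.sum() - 1.0) > 1e-9 or (f0 < 0).any():
        raise ValidationError("frequencies must be non-negative and sum to 1")
    w = f0 * np.exp(np.asarray(s, dtype=float) * duration)
    return w / w.sum()


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadArrays:
    """Compact per-sample read representation for UMI consensus calling.

    Reads are grouped contiguously by UMI.  ``site_codes[r, s]`` encodes the
    base observed at programmed site ``s+1`` in read ``r``: 0 = reference
    allele, 1 = alternate allele, 2/3 = either non-programmed base.
    Off-site substitution events are listed sparsely; ``off_base`` indexes
    which of the three non-reference bases was read.
    """

    umi_reads: np.ndarray  # (n_umis,) reads per UMI, all >= 1
    site_codes: np.ndarray  # (n_reads, 9) uint8 codes
    off_read: np.ndarray  # (n_events,) read index
    off_pos: np.ndarray  # (n_events,) 0-based amplicon position
    off_base: np.ndarray  # (n_events,) 0..2
    amplicon_length: int
    true_genotype: np.ndarray | None = None  # (n_umis,) index, if known

    @property
    def n_umis(self) -> int:
        return len(self.umi_reads)

    @property
    def n_reads(self) -> int:
        return int(self.umi_reads.sum())


@dataclass
class ReadRecord:
    """One synthetic amplicon read; the UMI rides in the read name."""

    name: str
    umi: str
    sequence: str


def _truncated_poisson(rate: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Poisson draw (every UMI is seen by >= 1 read)."""
    k = rng.poisson(rate, n)
    zeros = k == 0
    while zeros.any():
        k[zeros] = rng.poisson(rate, int(zeros.sum()))
        zeros = k == 0
    return k


def simulate_umi_sample(
    genotype_counts: np.ndarray,
    mean_reads: float = 5.0,
    per_base_error: float = 0.001,
    rng: np.random.Generator | int = 0,
    sites: Sequence[MutationSite] = DEFAULT_SITES,
    amplicon_length: int = len(REFERENCE_AMPLICON),
    contaminant_fraction: float = 0.0,
    contaminant_position: int = 280,
) -> ReadArrays:
    """Emit reads for one sample from per-genotype UMI counts.

    Each UMI (template molecule) carries one genotype and is read ``k``
    times, ``k`` ~ zero-truncated Poisson(``mean_reads``).  Every base of
    every read is substituted independently with probability
    ``per_base_error``; a substitution hits each of the three alternative
    bases equally, so at a programmed site 1/3 of errors produce the
    partner allele and 2/3 produce an off-target base.  Optionally a
    fraction of templates carry a fixed off-site contaminant mutation.
    """
    rng = np.random.default_rng(rng)
    sites = validate_sites(sites)
    genotype_counts = np.asarray(genotype_counts)
    if genotype_counts.min() < 0:
        raise ValidationError("genotype counts must be non-negative")
    n_umis = int(genotype_counts.sum())
    if n_umis < 1:
        raise ValidationError("need at least one UMI")
    site_pos = np.array([s.nucleotide_position - 1 for s in sites])

    umi_genotype = np.repeat(np.arange(len(genotype_counts)), genotype_counts)
    # random template order so genotypes are interleaved as in a real run
    rng.shuffle(umi_genotype)
    k = _truncated_poisson(mean_reads, n_umis, rng)
    n_reads = int(k.sum())
    read_geno = np.repeat(umi_genotype, k)

    bits = genotype_bit_matrix()
    codes = bits[read_geno].copy()  # start from true alleles (0/1)

    # errors at programmed sites
    err = rng.random((n_reads, N_SITES)) < per_base_error
    if err.any():
        rows, cols = np.nonzero(err)
        u = rng.integers(0, 3, len(rows))
        toggle = u == 0
        codes[rows[toggle], cols[toggle]] = 1 - codes[rows[toggle], cols[toggle]]
        other = ~toggle
        codes[rows[other], cols[other]] = (2 + (u[other] - 1)).astype(np.uint8)

    # errors at off-site positions
    non_site = np.setdiff1d(np.arange(amplicon_length), site_pos)
    m = rng.binomial(len(non_site), per_base_error, n_reads)
    off_read = np.repeat(np.arange(n_reads), m)
    off_pos = non_site[rng.integers(0, len(non_site), len(off_read))]
    off_base = rng.integers(0, 3, len(off_read)).astype(np.uint8)

    if contaminant_fraction > 0:
        hit = rng.random(n_umis) < contaminant_fraction
        if hit.any():
            offsets = np.cumsum(k) - k
            hit_reads = np.concatenate(
                [np.arange(offsets[i], offsets[i] + k[i]) for i in np.nonzero(hit)[0]]
            )
            off_read = np.concatenate([off_read, hit_reads])
            off_pos = np.concatenate(
                [off_pos, np.full(len(hit_reads), contaminant_position - 1)]
            )
            off_base = np.concatenate(
                [off_base, np.zeros(len(hit_reads), dtype=np.uint8)]
            )

    return ReadArrays(
        umi_reads=k,
        site_codes=codes.astype(np.uint8),
        off_read=off_read.astype(np.int64),
        off_pos=off_pos.astype(np.int64),
        off_base=off_base,
        amplicon_length=amplicon_length,
        true_genotype=umi_genotype,
    )


def simulate_competition_reads(
    landscape: FitnessLandscape,
    f0: np.ndarray,
    n_umis: int,
    mean_reads: float = 5.0,
    per_base_error: float = 0.001,
    duration: float = 1.0,
    seed: int | np.random.Generator = 0,
    **sample_kwargs,
) -> tuple[ReadArrays, ReadArrays]:
    """Simulate paired t0/t4 sequencing samples of one competition flask.

    UMIs are multinomial draws from the library frequencies at t0 and from
    the exponentially propagated frequencies at t4 (one competition unit =
    the 4-hour experiment by default).  The governing landscape must be
    fully observed (use the ground-truth generator or a floor-filled one).
    """
    if n_umis < 1:
        raise ValidationError("n_umis must be >= 1")
    rng = np.random.default_rng(seed)
    s = landscape.values
    if not np.isfinite(s).all():
        raise ValidationError("governing landscape must have no missing values")
    f_t = propagate_frequencies(f0, s, duration)
    counts0 = rng.multinomial(n_umis, f0)
    counts_t = rng.multinomial(n_umis, f_t)
    t0 = simulate_umi_sample(
        counts0, mean_reads, per_base_error, rng, **sample_kwargs
    )
    t4 = simulate_umi_sample(
        counts_t, mean_reads, per_base_error, rng, **sample_kwargs
    )
    return t0, t4


# ---------------------------------------------------------------------------
# FASTQ rendering
# ---------------------------------------------------------------------------


def _random_umis(n: int, rng: np.random.Generator) -> list[str]:
    """Unique random barcodes of length 5-12 (equimolar length mix)."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(5, 13))
        umi = "".join("ACGT"[b] for b in rng.integers(0, 4, length))
        if umi in seen:
            continue
        seen.add(umi)
        out.append(umi)
    return out


def arrays_to_records(
    arrays: ReadArrays,
    sites: Sequence[MutationSite] = DEFAULT_SITES,
    reference: str = REFERENCE_AMPLICON,
    seed: int | np.random.Generator = 0,
    name_prefix: str = "read",
) -> list[ReadRecord]:
    """Materialise full read sequences (with UMI strings) from array form."""
    rng = np.random.default_rng(seed)
    sites = validate_sites(sites)
    if len(reference) != arrays.amplicon_length:
        raise ValidationError("reference length does not match simulated amplicon")
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    site_pos = np.array([s.nucleotide_position - 1 for s in sites])
    ref_codes = np.array([_BASES.tolist().index(ref[p]) for p in site_pos])
    alt_codes = np.array(
        ["ACGT".index(s.alt_allele.upper()) for s in sites]
    )
    # code -> base index per site: 0 ref, 1 alt, 2/3 the two remaining bases
    code_to_base = np.empty((N_SITES, 4), dtype=np.uint8)
    for s in range(N_SITES):
        others = [b for b in range(4) if b not in (ref_codes[s], alt_codes[s])]
        code_to_base[s] = [ref_codes[s], alt_codes[s], others[0], others[1]]

    umis = _random_umis(arrays.n_umis, rng)
    read_umi = np.repeat(np.arange(arrays.n_umis), arrays.umi_reads)

    seqs = np.tile(ref, (arrays.n_reads, 1))
    for s in range(N_SITES):
        seqs[:, site_pos[s]] = _BASES[code_to_base[s][arrays.site_codes[:, s]]]
    # off-site substitutions: base index = off_base-th base that is not ref
    for r, p, b in zip(arrays.off_read, arrays.off_pos, arrays.off_base):
        others = [x for x in range(4) if _BASES[x] != ref[p]]
        seqs[r, p] = _BASES[others[b]]

    records = []
    for i in range(arrays.n_reads):
        umi = umis[read_umi[i]]
        records.append(
            ReadRecord(
                name=f"{name_prefix}{i}_UMI:{umi}",
                umi=umi,
                sequence=seqs[i].tobytes().decode(),
            )
        )
    return records


def write_fastq(records: Sequence[ReadRecord], path: str | Path) -> None:
    """Standard 4-line FASTQ with constant Phred+33 quality."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(
                f"@{rec.name}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n"
            )


def write_reference_fasta(path: str | Path, reference: str = REFERENCE_AMPLICON) -> None:
    with open(path, "w") as handle:
        handle.write(">amplicon\n")
        for i in range(0, len(reference), 60):
            handle.write(reference[i : i + 60] + "\n")
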