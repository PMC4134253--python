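"""Genetic diversity statistics for codominant genotypes and mtDNA sequences.

Implements the summary statistics used to characterise the park
population's genetic state: per-locus allele frequencies, observed and
unbiased expected heterozygosity (Nei 1978 gene diversity), the exact test
of Hardy-Weinberg proportions (conditional on allele counts, Guo &
Thompson statistic), and haplotype / nucleotide diversity of aligned
D-loop sequences with their standard (Nei 1987) sampling errors.

Genotypes live in a :class:`GenotypeMatrix` (individuals x loci, unordered
diploid allele pairs, missing entries allowed); sequences in a
:class:`SequenceSet` thin wrapper over Biopython ``SeqRecord`` objects.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencyTable",
    "LocusDiversity",
    "SequenceSet",
    "SequenceStats",
    "allele_frequencies",
    "heterozygosity",
    "hwe_exact_test",
    "haplotype_diversity",
    "nucleotide_diversity",
    "gene_diversity",
    "unbiased_gene_diversity",
]

MISSING = None

_VALID_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Individuals x loci table of unordered diploid allele pairs.

    ``genotypes[individual][locus]`` is either a 2-tuple of opaque allele
    labels or ``None`` for a missing (failed-amplification) entry.
    """

    individuals: list[str]
    loci: list[str]
    genotypes: dict[str, dict[str, Optional[tuple]]]

    def __post_init__(self) -> None:
        for ind in self.individuals:
            row = self.genotypes.get(ind, {})
            for locus, g in row.items():
                if g is not None and len(g) != 2:
                    raise ValueError(
                        f"genotype of {ind!r} at {locus!r} is not a diploid pair"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def genotypes_at(self, locus: str) -> list[tuple]:
        """Non-missing genotypes at one locus (order = individual order)."""
        out = []
        for ind in self.individuals:
            g = self.genotypes.get(ind, {}).get(locus)
            if g is not None:
                out.append(tuple(g))
        return out

    def genotype_counts(self, locus: str) -> dict[tuple, int]:
        """Unordered-pair genotype counts at one locus."""
        counts: dict[tuple, int] = {}
        for g in self.genotypes_at(locus):
            key = tuple(sorted(g, key=str))
            counts[key] = counts.get(key, 0) + 1
        return counts

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format frame with columns individual,locus,allele1,allele2
        (empty strings for missing entries)."""
        rows = []
        for ind in self.individuals:
            for locus in self.loci:
                g = self.genotypes.get(ind, {}).get(locus)
                a1, a2 = ("", "") if g is None else (str(g[0]), str(g[1]))
                rows.append((ind, locus, a1, a2))
        return pd.DataFrame(rows, columns=["individual", "locus", "allele1", "allele2"])


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequency spectra with their sample sizes.

    ``freqs[locus]`` maps allele label -> relative frequency (summing to 1);
    ``n_genotyped[locus]`` is the number of diploid individuals the
    frequencies were estimated from (0 for constructed spectra).
    """

    freqs: dict[str, dict[str, float]]
    n_genotyped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, spectrum in self.freqs.items():
            total = sum(spectrum.values())
            if any(p < 0 for p in spectrum.values()):
                raise ValueError(f"negative allele frequency at {locus!r}")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"allele frequencies at {locus!r} sum to {total!r}, not 1"
                )

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def gene_diversity(self, locus: str) -> float:
        """Plain expected heterozygosity 1 - sum p^2 at one locus."""
        return gene_diversity(self.freqs[locus].values())

    def mean_gene_diversity(self) -> float:
        return float(np.mean([self.gene_diversity(l) for l in self.loci]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (locus, allele, p)
            for locus, spectrum in self.freqs.items()
            for allele, p in spectrum.items()
        ]
        return pd.DataFrame(rows, columns=["locus", "allele", "frequency"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleFrequencyTable":
        freqs: dict[str, dict[str, float]] = {}
        for locus, sub in df.groupby("locus", sort=False):
            freqs[str(locus)] = {
                str(a): float(p) for a, p in zip(sub["allele"], sub["frequency"])
            }
        return cls(freqs=freqs)


@dataclass
class LocusDiversity:
    """Per-locus diversity summary: Ho, unbiased He and HWE exact p."""

    locus: str
    n_genotyped: int
    ho: float
    he: float
    hwe_p: Optional[float] = None
    monomorphic: bool = False


@dataclass
class SequenceSet:
    """Aligned equal-length sequences (e.g. a mtDNA D-loop alignment)."""

    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if self.records:
            L = len(self.records[0].seq)
            for rec in self.records:
                if len(rec.seq) != L:
                    raise ValueError(
                        f"ragged alignment: {rec.id!r} has length "
                        f"{len(rec.seq)}, expected {L}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].seq) if self.records else 0

    def as_strings(self) -> list[str]:
        return [str(rec.seq).upper() for rec in self.records]


@dataclass
class SequenceStats:
    """Haplotype/nucleotide diversity of a sequence sample."""

    n_sequences: int
    alignment_length: int
    n_haplotypes: Optional[int] = None
    haplotype_diversity: Optional[float] = None
    haplotype_diversity_se: Optional[float] = None
    nucleotide_diversity: Optional[float] = None
    nucleotide_diversity_se: Optional[float] = None


# ---------------------------------------------------------------------------
# heterozygosity


def gene_diversity(frequencies: Iterable[float]) -> float:
    """Plain gene diversity 1 - sum p_i^2 (drift bookkeeping form)."""
    p = np.asarray(list(frequencies), dtype=float)
    return float(1.0 - np.sum(p * p))


def unbiased_gene_diversity(frequencies: Iterable[float], n: int) -> float:
    """Nei (1978) small-sample unbiased expected heterozygosity,
    ``2n/(2n-1) * (1 - sum p^2)`` with *n* diploid individuals."""
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    if n == 1:
        # 2n/(2n-1) = 2; with a single heterozygote this gives He = 1.
        pass
    return float(2 * n / (2 * n - 1) * gene_diversity(frequencies))


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencyTable:
    """Estimate per-locus allele frequencies by gene counting.

    Missing genotypes are excluded per locus (sample sizes therefore vary
    among loci); loci with no genotyped individuals are omitted.
    """
    if not g.individuals or not g.loci:
        raise ValueError("empty genotype matrix")
    freqs: dict[str, dict[str, float]] = {}
    ns: dict[str, int] = {}
    for locus in g.loci:
        genos = g.genotypes_at(locus)
        if not genos:
            continue
        counts: dict[str, int] = {}
        for a1, a2 in genos:
            counts[str(a1)] = counts.get(str(a1), 0) + 1
            counts[str(a2)] = counts.get(str(a2), 0) + 1
        total = 2 * len(genos)
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
        ns[locus] = len(genos)
    if not freqs:
        raise ValueError("no genotyped individuals at any locus")
    return AlleleFrequencyTable(freqs=freqs, n_genotyped=ns)


def heterozygosity(g: GenotypeMatrix, hwe: bool = False) -> list[LocusDiversity]:
    """Observed and unbiased expected heterozygosity per locus.

    Ho is the fraction of genotyped individuals that are heterozygous; He
    is the Nei (1978) unbiased gene diversity.  Monomorphic loci are
    reported with He = 0 and flagged.  With ``hwe=True`` the exact
    Hardy-Weinberg test p-value is attached per polymorphic locus.
    """
    table = allele_frequencies(g)
    out = []
    for locus in g.loci:
        if locus not in table.freqs:
            continue
        genos = g.genotypes_at(locus)
        n = len(genos)
        ho = sum(1 for a1, a2 in genos if str(a1) != str(a2)) / n
        spectrum = table.freqs[locus]
        mono = len(spectrum) < 2
        he = 0.0 if mono else unbiased_gene_diversity(spectrum.values(), n)
        p = None
        if hwe:
            p = hwe_exact_test(g.genotype_counts(locus)).p_value
        out.append(
            LocusDiversity(
                locus=locus, n_genotyped=n, ho=ho, he=he, hwe_p=p, monomorphic=mono
            )
        )
    return out


def diversity_table(g: GenotypeMatrix, hwe: bool = True) -> pd.DataFrame:
    """Per-locus diversity report shaped like a standard summary table
    (locus, n genotyped, Ho, He, HWE p), with a mean row over polymorphic
    loci appended."""
    rows = heterozygosity(g, hwe=hwe)
    poly = [r for r in rows if not r.monomorphic]
    return pd.DataFrame(
        {
            "locus": [r.locus for r in rows] + ["Mean"],
            "n_genotyped": [float(r.n_genotyped) for r in rows] + [np.nan],
            "ho": [np.nan if r.monomorphic else r.ho for r in rows]
            + [float(np.mean([r.ho for r in poly])) if poly else np.nan],
            "he": [np.nan if r.monomorphic else r.he for r in rows]
            + [float(np.mean([r.he for r in poly])) if poly else np.nan],
            "hwe_p": [
                np.nan if (r.monomorphic or r.hwe_p is None) else r.hwe_p
                for r in rows
            ]
            + [np.nan],
        }
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


@dataclass
class HWETestResult:
    """Exact-test outcome; ``mc_se`` is set on the Monte-Carlo path.

    ``p_strict`` is the probability of tables *strictly* less probable
    than the observed one; with an independent uniform u, the randomised
    statistic ``p_strict + u (p_value - p_strict)`` is exactly U(0, 1)
    under the null (useful for calibration checks of a discrete test).
    """

    p_value: float
    method: str  # "enumeration" | "monte-carlo" | "monomorphic"
    n_tables: Optional[int] = None
    mc_se: Optional[float] = None
    p_strict: Optional[float] = None


def _log_table_prob(het_count: int, genotype_counts: Sequence[int], n: int,
                    log_const: float) -> float:
    # log P(table | allele counts) = log n! + H log 2 - sum log n_ij! + const
    lp = math.lgamma(n + 1) + het_count * math.log(2.0) + log_const
    for c in genotype_counts:
        lp -= math.lgamma(c + 1)
    return lp


def _table_count_bound(allele_counts: Sequence[int], cap: int) -> int:
    """Cheap upper bound on the number of genotype tables compatible with
    the allele counts (product of per-pair choice counts over the free
    pairs; row-closing pairs are forced).  Saturates at ``cap + 1``."""
    k = len(allele_counts)
    bound = 1
    for i in range(k):
        for j in range(i, k):
            if j == k - 1:  # forced by row closure
                continue
            if i == j:
                bound *= allele_counts[i] // 2 + 1
            else:
                bound *= min(allele_counts[i], allele_counts[j]) + 1
            if bound > cap:
                return cap + 1
    return bound


def _enumerate_tables(allele_counts: list[int], cap: int):
    """Yield all genotype-count tables consistent with the allele counts.

    A table is a dict {(i,j): count} over ordered index pairs i<=j.  Yields
    (counts_list, het_count) tuples; raises ``OverflowError`` once more
    than ``cap`` tables have been produced.
    """
    k = len(allele_counts)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    produced = 0

    def rec(idx: int, remaining: list[int], current: list[int], hets: int):
        nonlocal produced
        if idx == len(pairs):
            produced += 1
            if produced > cap:
                raise OverflowError
            yield list(current), hets
            return
        i, j = pairs[idx]
        if i == j == k - 1:
            # final pair: homozygote count is forced
            if remaining[i] % 2:
                return
            choices = [remaining[i] // 2]
        elif j == k - 1 and i < j:
            # last pair of row i: remaining copies of allele i are forced here
            c = remaining[i]
            if c > remaining[j]:
                return
            choices = [c]
        elif i == j:
            choices = range(remaining[i] // 2 + 1)
        else:
            choices = range(min(remaining[i], remaining[j]) + 1)
        for c in choices:
            if i == j:
                remaining[i] -= 2 * c
            else:
                remaining[i] -= c
                remaining[j] -= c
            current.append(c)
            yield from rec(idx + 1, remaining, current, hets + (c if i != j else 0))
            current.pop()
            if i == j:
                remaining[i] += 2 * c
            else:
                remaining[i] += c
                remaining[j] += c

    yield from rec(0, list(allele_counts), [], 0)


def hwe_exact_test(
    genotype_counts: Mapping[tuple, int],
    max_enumeration: int = 1_000_000,
    mc_rounds: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> HWETestResult:
    """Exact test of Hardy-Weinberg proportions, conditional on allele counts.

    The test statistic is the conditional probability of the genotype
    table itself; the p-value is the total probability of tables no more
    probable than the observed one.  Full enumeration is used when the
    number of compatible tables does not exceed ``max_enumeration``;
    otherwise a Monte-Carlo version with ``mc_rounds`` random tables drawn
    by permuting the allele copies, reporting the binomial standard error.

    Parameters
    ----------
    genotype_counts
        Mapping from unordered allele pair (2-tuples) to count, e.g.
        ``{("A", "A"): 3, ("A", "B"): 0, ("B", "B"): 3}``.
    """
    counts = {tuple(sorted(k, key=str)): int(v) for k, v in genotype_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative genotype counts")
    n = sum(counts.values())
    if n < 1:
        raise ValueError("empty genotype table")

    alleles = sorted({a for pair in counts for a in pair}, key=str)
    if len(alleles) < 2:
        return HWETestResult(p_value=1.0, method="monomorphic")
    idx = {a: i for i, a in enumerate(alleles)}
    allele_counts = [0] * len(alleles)
    for (a1, a2), c in counts.items():
        allele_counts[idx[a1]] += c
        allele_counts[idx[a2]] += c

    # constant part: sum log a_c! - log (2n)!
    log_const = sum(math.lgamma(c + 1) for c in allele_counts) - math.lgamma(2 * n + 1)

    obs = [0] * (len(alleles) * (len(alleles) + 1) // 2)
    pairs = [(i, j) for i in range(len(alleles)) for j in range(i, len(alleles))]
    pair_index = {p: t for t, p in enumerate(pairs)}
    het_obs = 0
    for (a1, a2), c in counts.items():
        i, j = sorted((idx[a1], idx[a2]))
        obs[pair_index[(i, j)]] = c
        if i != j:
            het_obs += c
    lp_obs = _log_table_prob(het_obs, obs, n, log_const)

    if _table_count_bound(allele_counts, max_enumeration) <= max_enumeration:
        try:
            total = 0.0
            p_sum = 0.0
            strict_sum = 0.0
            n_tables = 0
            for tbl, hets in _enumerate_tables(allele_counts, max_enumeration):
                lp = _log_table_prob(hets, tbl, n, log_const)
                pr = math.exp(lp)
                total += pr
                n_tables += 1
                if lp <= lp_obs + 1e-10:
                    p_sum += pr
                    if lp < lp_obs - 1e-10:
                        strict_sum += pr
            # total should be 1 up to float error; normalise defensively
            return HWETestResult(
                p_value=min(1.0, p_sum / total), method="enumeration",
                n_tables=n_tables, p_strict=min(1.0, strict_sum / total),
            )
        except OverflowError:  # pragma: no cover - bound is an upper bound
            pass

    rng = np.random.default_rng(0) if rng is None else rng
    copies = np.repeat(np.arange(len(alleles)), allele_counts)
    hits = 0
    n_pairs = len(pairs)
    het_idx = np.array([t for t, (i, j) in enumerate(pairs) if i != j])
    for _ in range(mc_rounds):
        rng.shuffle(copies)
        a = np.minimum(copies[0::2], copies[1::2])
        b = np.maximum(copies[0::2], copies[1::2])
        flat = a * len(alleles) - a * (a - 1) // 2 + (b - a)
        tbl = np.bincount(flat, minlength=n_pairs)
        hets = int(tbl[het_idx].sum())
        lp = _log_table_prob(hets, tbl.tolist(), n, log_const)
        if lp <= lp_obs + 1e-10:
            hits += 1
    # +1 smoothing keeps the p-value in (0, 1] and includes the observed table
    p = (hits + 1) / (mc_rounds + 1)
    se = math.sqrt(p * (1 - p) / mc_rounds)
    return HWETestResult(p_value=p, method="monte-carlo", mc_se=se)


# ---------------------------------------------------------------------------
# sequence diversity


def _clean_sequences(seqs: SequenceSet, drop_incomplete: bool = True) -> list[str]:
    strings = seqs.as_strings()
    if drop_incomplete:
        kept = [s for s in strings if set(s) <= _VALID_BASES]
        return kept
    return strings


def haplotype_diversity(seqs: SequenceSet) -> SequenceStats:
    """Haplotype (gene) diversity Hd with its Nei (1987) standard error.

    Haplotypes are defined on the full alignment; sequences containing
    gaps or ambiguous bases are dropped.  Hd = n/(n-1) (1 - sum p_i^2).
    """
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    strings = _clean_sequences(seqs)
    n = len(strings)
    if n < 2:
        raise ValueError("need >= 2 complete sequences for haplotype diversity")
    counts = pd.Series(strings).value_counts()
    p = counts.to_numpy(dtype=float) / n
    sum2, sum3 = float(np.sum(p**2)), float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - sum2)
    var = (
        2.0
        / (n * (n - 1))
        * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return SequenceStats(
        n_sequences=n,
        alignment_length=seqs.alignment_length,
        n_haplotypes=int(len(counts)),
        haplotype_diversity=hd,
        haplotype_diversity_se=math.sqrt(max(var, 0.0)),
    )


def nucleotide_diversity(seqs: SequenceSet) -> SequenceStats:
    """Nucleotide diversity: mean per-site pairwise difference.

    Sites with gaps or ambiguous bases are excluded pairwise; each pair is
    normalised by its own number of comparable sites, and pi is the
    average over the n(n-1)/2 pairs.  The SE is from the standard total
    variance formula (stochastic + sampling, Nei 1987).
    """
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences for nucleotide diversity")
    strings = seqs.as_strings()
    n = len(strings)
    L = seqs.alignment_length
    arr = np.frombuffer("".join(strings).encode(), dtype="S1").reshape(n, L)
    valid = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    per_pair = []
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        L_ij = int(both.sum())
        if L_ij == 0:
            raise ValueError(f"sequences {i} and {j} share no comparable sites")
        d = int(np.sum((arr[i] != arr[j]) & both))
        per_pair.append(d / L_ij)
    pi = float(np.mean(per_pair))
    var = (n + 1) / (3 * (n - 1)) * pi / L + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) * pi**2
    return SequenceStats(
        n_sequences=n,
        alignment_length=L,
        nucleotide_diversity=pi,
        nucleotide_diversity_se=math.sqrt(max(var, 0.0)),
    )


def sequence_summary(seqs: SequenceSet) -> SequenceStats:
    """Combined haplotype + nucleotide diversity of one alignment."""
    hap = haplotype_diversity(seqs)
    nuc = nucleotide_diversity(seqs)
    return SequenceStats(
        n_sequences=hap.n_sequences,
        alignment_length=hap.alignment_length,
        n_haplotypes=hap.n_haplotypes,
        haplotype_diversity=hap.haplotype_diversity,
        haplotype_diversity_se=hap.haplotype_diversity_se,
        nucleotide_diversity=nuc.nucleotide_diversity,
        nucleotide_diversity_se=nuc.nucleotide_diversity_se,
    )
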