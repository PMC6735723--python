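"""From codon alignments to site frequency spectra.

Takes per-gene codon alignments (ingroup chromosomes plus one outgroup
sequence), classifies each codon column as monomorphic / polymorphic /
divergent / excluded, counts synonymous and nonsynonymous site
opportunities by Nei-Gojobori fractional counting, polarizes derived
alleles against the outgroup, and projects polymorphic sites down to a
common sample size by hypergeometric sampling.

Conventions
-----------
* Coordinates are 0-based; ``codon_index * 3 + position_in_codon`` is the
  nucleotide offset in the alignment.
* Mutations to stop codons are excluded from both opportunity classes, so
  a codon's opportunities sum to 3 minus the stop-reachable fraction.
* Codons segregating at two or more nucleotide positions, codons where a
  nucleotide position carries more than two alleles, and codons where the
  outgroup allele matches neither ingroup allele are excluded with a
  reason code (pathway/polarization ambiguity).
* A codon both polymorphic and divergent counts as polymorphic only.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from scipy.stats import hypergeom

from .spectra import SpectrumSet

__all__ = [
    "CodonAlignment",
    "SiteRecord",
    "count_site_opportunities",
    "classify_segregating_site",
    "project_site",
    "build_spectrum",
    "read_codon_alignment",
]

VALID_BASES = frozenset("ACGT")
ALPHABET = frozenset("ACGTN-")

# Site status codes
MONOMORPHIC = "monomorphic"
POLY_SYN = "polymorphic_syn"
POLY_NONSYN = "polymorphic_nonsyn"
DIV_SYN = "divergent_syn"
DIV_NONSYN = "divergent_nonsyn"
EXCLUDED = "excluded"


@dataclass
class CodonAlignment:
    """An in-frame alignment of ingroup sequences plus one outgroup."""

    gene_id: str
    ingroup_seqs: list[str]
    outgroup_seq: str
    genetic_code: str = "Standard"

    def __post_init__(self) -> None:
        self.ingroup_seqs = [s.upper() for s in self.ingroup_seqs]
        self.outgroup_seq = self.outgroup_seq.upper()
        if not self.ingroup_seqs:
            raise ValueError(f"{self.gene_id}: no ingroup sequences")
        L = len(self.ingroup_seqs[0])
        for s in self.ingroup_seqs + [self.outgroup_seq]:
            if len(s) != L:
                raise ValueError(f"{self.gene_id}: sequences of unequal length")
            bad = set(s) - ALPHABET
            if bad:
                raise ValueError(f"{self.gene_id}: invalid characters {bad}")
        if L % 3 != 0:
            raise ValueError(f"{self.gene_id}: length {L} not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.ingroup_seqs[0]) // 3

    @property
    def n_ingroup(self) -> int:
        return len(self.ingroup_seqs)

    def codon_column(self, idx: int) -> tuple[list[str], str]:
        sl = slice(3 * idx, 3 * idx + 3)
        return [s[sl] for s in self.ingroup_seqs], self.outgroup_seq[sl]

    def table(self) -> CodonTable.CodonTable:
        return CodonTable.unambiguous_dna_by_name[self.genetic_code]

    def has_premature_stop(self) -> bool:
        """True if any ingroup sequence carries a stop before the last codon."""
        stops = set(self.table().stop_codons)
        for s in self.ingroup_seqs:
            for i in range(self.n_codons - 1):
                if s[3 * i : 3 * i + 3] in stops:
                    return True
        return False


@dataclass
class SiteRecord:
    """Per-codon classification record.

    ``syn_opportunity``/``nonsyn_opportunity`` are fractional site counts
    for the whole codon (they sum to at most 3).  ``derived_count`` is
    present only for polymorphic sites and ``position_in_codon`` marks the
    segregating (or divergent) nucleotide position.
    """

    gene_id: str
    codon_index: int
    status: str
    syn_opportunity: float = 0.0
    nonsyn_opportunity: float = 0.0
    position_in_codon: int = 0
    derived_count: Optional[int] = None
    sample_size: int = 0
    reason: Optional[str] = None


def count_site_opportunities(
    codon: str, genetic_code: str = "Standard"
) -> tuple[float, float]:
    """Nei-Gojobori fractional synonymous/nonsynonymous opportunities.

    Each of the nine single-base changes contributes 1/3 of a site to the
    synonymous or nonsynonymous class according to whether the encoded
    amino acid changes; changes creating a stop codon contribute to
    neither class.

    Returns ``(syn, nonsyn)`` with ``syn + nonsyn = 3 - stop_fraction``.
    """
    codon = codon.upper()
    table = CodonTable.unambiguous_dna_by_name[genetic_code]
    if len(codon) != 3 or set(codon) - VALID_BASES:
        raise ValueError(f"codon {codon!r} contains ambiguous or gap characters")
    if codon in table.stop_codons:
        raise ValueError(f"codon {codon!r} is a stop codon")
    aa = table.forward_table[codon]
    syn = nonsyn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in table.stop_codons:
                continue
            if table.forward_table[mut] == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


def _mean_opportunities(
    codons: Sequence[str], genetic_code: str
) -> tuple[float, float]:
    ops = [count_site_opportunities(c, genetic_code) for c in codons]
    return float(np.mean([o[0] for o in ops])), float(np.mean([o[1] for o in ops]))


def classify_segregating_site(
    column_codons: Sequence[str],
    outgroup_codon: str,
    gene_id: str = "",
    codon_index: int = 0,
    genetic_code: str = "Standard",
) -> SiteRecord:
    """Classify one codon column of an alignment.

    The derived allele is the ingroup allele that differs from the
    outgroup allele at the segregating position.  Sites with a missing
    (gap/N) outgroup codon are excluded as missing data; so are stop
    codons, multi-allelic positions, codons segregating at more than one
    position, and polarization failures.
    """
    table = CodonTable.unambiguous_dna_by_name[genetic_code]
    m = len(column_codons)
    rec = SiteRecord(gene_id=gene_id, codon_index=codon_index,
                     status=EXCLUDED, sample_size=m)

    def excl(reason: str) -> SiteRecord:
        rec.status = EXCLUDED
        rec.reason = reason
        return rec

    column_codons = [c.upper() for c in column_codons]
    outgroup_codon = outgroup_codon.upper()
    if set(outgroup_codon) - VALID_BASES:
        return excl("outgroup_missing")
    if any(set(c) - VALID_BASES for c in column_codons):
        return excl("ingroup_missing")
    stops = set(table.stop_codons)
    if outgroup_codon in stops or any(c in stops for c in column_codons):
        return excl("stop_codon")

    # segregating nucleotide positions within the ingroup
    seg_positions = []
    for pos in range(3):
        alleles = {c[pos] for c in column_codons}
        if len(alleles) > 2:
            return excl("multiallelic")
        if len(alleles) == 2:
            seg_positions.append(pos)
    if len(seg_positions) > 1:
        return excl("multiple_segregating_positions")

    rec.syn_opportunity, rec.nonsyn_opportunity = _mean_opportunities(
        column_codons, genetic_code
    )

    if len(seg_positions) == 1:
        pos = seg_positions[0]
        counts = Counter(c[pos] for c in column_codons)
        (a1, _), (a2, _) = counts.most_common(2)
        out_allele = outgroup_codon[pos]
        if out_allele not in (a1, a2):
            return excl("polarization_failure")
        derived = a2 if out_allele == a1 else a1
        # amino-acid effect of the segregating change, in ingroup context
        ctx = column_codons[0]
        c_anc = ctx[:pos] + out_allele + ctx[pos + 1 :]
        c_der = ctx[:pos] + derived + ctx[pos + 1 :]
        syn_change = table.forward_table[c_anc] == table.forward_table[c_der]
        rec.status = POLY_SYN if syn_change else POLY_NONSYN
        rec.position_in_codon = pos
        rec.derived_count = counts[derived]
        return rec

    # monomorphic ingroup: compare consensus codon against the outgroup
    cons = column_codons[0]
    diffs = [p for p in range(3) if cons[p] != outgroup_codon[p]]
    if not diffs:
        rec.status = MONOMORPHIC
        return rec
    if len(diffs) > 1:
        return excl("multiple_divergent_positions")
    pos = diffs[0]
    syn_change = table.forward_table[cons] == table.forward_table[outgroup_codon]
    rec.status = DIV_SYN if syn_change else DIV_NONSYN
    rec.position_in_codon = pos
    return rec


def project_site(
    m: int,
    d: int,
    n_target: int,
    mode: str = "expected",
    rng: Optional[np.random.Generator] = None,
):
    """Down-sample a polymorphic site from ``m`` to ``n_target`` chromosomes.

    ``expected`` mode returns the exact hypergeometric probability vector
    over derived counts ``0..n_target``; ``random`` mode draws one count
    without replacement.  Projected counts of 0 or ``n_target`` fall out
    of the polymorphic SFS.
    """
    if n_target > m:
        raise ValueError(f"n_target={n_target} exceeds observed alleles m={m}")
    if not 0 <= d <= m:
        raise ValueError(f"derived count d={d} outside [0, {m}]")
    if mode == "expected":
        k = np.arange(n_target + 1)
        return hypergeom.pmf(k, m, d, n_target)
    if mode == "random":
        if rng is None:
            rng = np.random.default_rng()
        return int(rng.hypergeometric(d, m - d, n_target))
    raise ValueError(f"unknown projection mode {mode!r}")


def build_spectrum(
    alignment: CodonAlignment,
    n_target: Optional[int] = None,
    mode: str = "expected",
    seed: Optional[int] = None,
    fold: bool = False,
    exclusion_counts: Optional[Counter] = None,
) -> SpectrumSet:
    """Turn a codon alignment into a :class:`SpectrumSet`.

    Parameters
    ----------
    n_target : int, optional
        Common sample size after down-sampling (defaults to the number of
        ingroup sequences).  Polymorphic sites are projected with
        :func:`project_site`; ``mode='expected'`` spreads the exact
        hypergeometric mass over SFS classes (deterministic),
        ``mode='random'`` draws a seeded single count per site.
    fold : bool
        Return the folded spectrum.
    exclusion_counts : collections.Counter, optional
        If given, incremented with per-reason exclusion tallies.

    Raises
    ------
    ValueError
        If any ingroup sequence carries a premature stop codon (the
        gene-level filter) or ``n_target`` exceeds the sample size.
    """
    if alignment.has_premature_stop():
        raise ValueError(
            f"{alignment.gene_id}: premature stop codon in an ingroup sequence"
        )
    m = alignment.n_ingroup
    if n_target is None:
        n_target = m
    if n_target > m:
        raise ValueError(f"n_target={n_target} exceeds sample size m={m}")
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    rng = np.random.default_rng(seed)

    n = n_target
    sfs_syn = np.zeros(n - 1)
    sfs_nonsyn = np.zeros(n - 1)
    Ls = Ln = 0.0
    Ds = Dn = 0.0
    retained = 0
    for idx in range(alignment.n_codons):
        codons, out_codon = alignment.codon_column(idx)
        rec = classify_segregating_site(
            codons, out_codon, alignment.gene_id, idx, alignment.genetic_code
        )
        if rec.status == EXCLUDED:
            if exclusion_counts is not None:
                exclusion_counts[rec.reason] += 1
            continue
        retained += 1
        Ls += rec.syn_opportunity
        Ln += rec.nonsyn_opportunity
        if rec.status == DIV_SYN:
            Ds += 1
        elif rec.status == DIV_NONSYN:
            Dn += 1
        elif rec.status in (POLY_SYN, POLY_NONSYN):
            target = sfs_syn if rec.status == POLY_SYN else sfs_nonsyn
            if mode == "expected":
                pmf = project_site(m, rec.derived_count, n, mode="expected")
                target += pmf[1:n]
            else:
                k = project_site(m, rec.derived_count, n, mode="random", rng=rng)
                if 1 <= k <= n - 1:
                    target[k - 1] += 1
    if retained == 0:
        warnings.warn(f"{alignment.gene_id}: no retained sites; spectrum is empty")
    spec = SpectrumSet(
        n=n, Ls=Ls, Ln=Ln, sfs_syn=sfs_syn, sfs_nonsyn=sfs_nonsyn,
        Ds=Ds, Dn=Dn, folded=False, name=alignment.gene_id,
    )
    if fold:
        from .spectra import fold_spectrum

        spec = fold_spectrum(spec)
    return spec


def read_codon_alignment(
    path, outgroup_tag: str = "outgroup", gene_id: Optional[str] = None,
    genetic_code: str = "Standard",
) -> CodonAlignment:
    """Read a per-gene FASTA codon alignment.

    The record whose id contains ``outgroup_tag`` is taken as the outgroup;
    all other records form the ingroup sample.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    outgroup = [r for r in records if outgroup_tag in r.id]
    if len(outgroup) != 1:
        raise ValueError(
            f"{path}: expected exactly one record tagged {outgroup_tag!r}, "
            f"found {len(outgroup)}"
        )
    ingroup = [str(r.seq) for r in records if outgroup_tag not in r.id]
    return CodonAlignment(
        gene_id=gene_id or path.stem,
        ingroup_seqs=ingroup,
        outgroup_seq=str(outgroup[0].seq),
        genetic_code=genetic_code,
    )
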