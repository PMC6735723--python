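"""Gene- and residue-level covariates: normalization, discretization, mapping.

Residue-level structural features (relative solvent accessibility,
secondary structure, intrinsic disorder, active sites) and gene-level
covariates (length, expression, recombination, introns, PPI degree, ...)
are normalized, discretized into ordered analysis categories, and mapped
onto codon alignments so that per-category site frequency spectra can be
pooled and fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .spectra import SpectrumSet, aggregate_spectra

__all__ = [
    "MAX_ASA",
    "GRANTHAM_VOLUME",
    "GRANTHAM_POLARITY",
    "SS_CLASSES",
    "SS_COLLAPSE",
    "CategoryAssignment",
    "compute_rsa",
    "classify_exposure",
    "flag_disordered",
    "equal_count_bins",
    "map_structure_to_alignment",
    "grantham_class",
    "category_spectra",
]

# Theoretical maximum solvent-accessible surface areas per residue (A^2),
# used to normalize raw accessibility into RSA.  Configurable: pass your
# own table to compute_rsa.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Grantham (1974) amino-acid property scales.
GRANTHAM_VOLUME: dict[str, float] = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0,
    "Q": 85.0, "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0,
    "L": 111.0, "K": 119.0, "M": 105.0, "F": 132.0, "P": 32.5,
    "S": 32.0, "T": 61.0, "W": 170.0, "Y": 136.0, "V": 84.0,
}
GRANTHAM_POLARITY: dict[str, float] = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}

SS_CLASSES = ("sheet", "helix", "loop")

# Collapse of the 8-state DSSP alphabet onto {sheet, helix, loop}.
SS_COLLAPSE: dict[str, str] = {
    "E": "sheet", "B": "sheet",
    "H": "helix", "G": "helix", "I": "helix",
    "T": "loop", "S": "loop", "C": "loop", "-": "loop", " ": "loop",
    "sheet": "sheet", "helix": "helix", "loop": "loop",
}

EXPOSURE_THRESHOLD = 0.05  # buried: RSA < 0.05; exposed: RSA >= 0.05


@dataclass
class CategoryAssignment:
    """Mapping of analysis units (genes or sites) into ordered categories.

    ``labels`` carries the total order used by trend tests; every
    assigned unit has exactly one label.
    """

    scheme_name: str
    unit: str  # "gene" or "site"
    labels: list[str]
    membership: pd.Series  # unit id -> label

    def __post_init__(self) -> None:
        if self.unit not in ("gene", "site"):
            raise ValueError("unit must be 'gene' or 'site'")
        unknown = set(self.membership.unique()) - set(self.labels)
        if unknown:
            raise ValueError(f"membership uses labels not in order: {unknown}")

    def rank(self, label: str) -> int:
        return self.labels.index(label)

    def units_by_label(self) -> dict[str, list]:
        out: dict[str, list] = {lab: [] for lab in self.labels}
        for unit_id, lab in self.membership.items():
            out[lab].append(unit_id)
        return out

    def sizes(self) -> dict[str, int]:
        vc = self.membership.value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in self.labels}


def compute_rsa(sa: float, residue: Optional[str] = None,
                max_asa: Optional[float] = None,
                table: Mapping[str, float] = MAX_ASA) -> float:
    """Relative solvent accessibility: raw area / maximum area, clamped to [0,1].

    Either pass ``max_asa`` directly or a one-letter ``residue`` looked up
    in ``table``.
    """
    if sa < 0:
        raise ValueError("solvent-accessible area must be >= 0")
    if max_asa is None:
        if residue is None:
            raise ValueError("need residue letter or explicit max_asa")
        residue = residue.upper()
        if residue not in table:
            raise KeyError(residue)
        max_asa = table[residue]
    if max_asa <= 0:
        raise ValueError("max accessible area must be > 0")
    return float(min(1.0, sa / max_asa))


def classify_exposure(rsa: float) -> str:
    """Buried (RSA < 0.05) vs exposed (RSA >= 0.05)."""
    if not 0.0 <= rsa <= 1.0:
        raise ValueError("RSA must lie in [0, 1]")
    return "buried" if rsa < EXPOSURE_THRESHOLD else "exposed"


def flag_disordered(
    residues: pd.DataFrame,
    disorder_col: str = "disorder_p",
    gene_col: str = "gene_id",
    quantile: float = 0.75,
) -> tuple[pd.Series, pd.Series]:
    """Top-quartile disorder rule across the whole proteome.

    The threshold is the 75th percentile (linear interpolation) of all
    residue disorder values; a residue is disordered iff its value is
    strictly above the threshold (tie-safe: if all values are equal,
    nothing is flagged).  Returns ``(per_residue_flag, per_gene_proportion)``.
    """
    vals = residues[disorder_col].to_numpy(dtype=float)
    if vals.size < 4:
        raise ValueError("need at least 4 residues proteome-wide")
    threshold = float(np.percentile(vals, 100 * quantile))
    flags = residues[disorder_col] > threshold
    prop = flags.groupby(residues[gene_col]).mean()
    return flags, prop


def equal_count_bins(
    values: pd.Series,
    k: int,
    zero_special: bool = False,
    scheme_name: str = "scheme",
    unit: str = "gene",
) -> CategoryAssignment:
    """Quantile (equal-count) discretization into ``k`` ordered categories.

    Ties share a bin (assigned to the lower-quantile side, as quantile
    cut points group equal values together).  With ``zero_special``,
    units whose value is exactly 0 form their own first category and the
    remaining units are split into ``k - 1`` quantile bins — the layout
    used for RSA, where totally buried residues (RSA = 0) get a dedicated
    category.  If ties prevent ``k`` nonempty bins, the number of bins is
    reduced with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    values = values.dropna()
    if len(values) < k:
        raise ValueError(f"need at least k={k} units, got {len(values)}")
    width = len(str(k))
    labels: list[str] = []
    membership = pd.Series(index=values.index, dtype=object)
    if zero_special:
        zero_mask = values == 0
        zero_label = f"{scheme_name}_{0:0{width}d}_zero"
        labels.append(zero_label)
        membership[zero_mask] = zero_label
        rest = values[~zero_mask]
        n_bins = k - 1
    else:
        rest = values
        n_bins = k
    if len(rest) > 0:
        codes, bins = pd.qcut(rest, n_bins, labels=False, retbins=True,
                              duplicates="drop")
        got = int(codes.max()) + 1
        if got < n_bins:
            warnings.warn(
                f"{scheme_name}: ties reduced {n_bins} bins to {got}"
            )
        offset = 1 if zero_special else 0
        bin_labels = [
            f"{scheme_name}_{j + offset:0{width}d}" for j in range(got)
        ]
        labels.extend(bin_labels)
        membership[rest.index] = [bin_labels[c] for c in codes]
    return CategoryAssignment(
        scheme_name=scheme_name, unit=unit, labels=labels,
        membership=membership.astype(str),
    )


def map_structure_to_alignment(
    protein_aligned: str,
    structure_aligned: str,
    features: pd.DataFrame,
    residue_col: str = "residue_index",
    require_match: bool = True,
) -> pd.DataFrame:
    """Transfer per-residue structure features onto protein (codon) positions.

    ``protein_aligned``/``structure_aligned`` are the two rows of a
    pairwise alignment (gaps as '-').  Features indexed by the structure's
    residue order gain a ``codon_index`` column pointing into the protein;
    residues in gapped (or mismatching, when ``require_match``) columns
    are dropped and counted in the ``n_unmapped`` attribute.
    """
    if len(protein_aligned) != len(structure_aligned):
        raise ValueError("aligned sequences have different lengths")
    mapping: dict[int, int] = {}  # structure residue index -> codon index
    pi = si = 0
    for a, b in zip(protein_aligned.upper(), structure_aligned.upper()):
        if a != "-" and b != "-" and (not require_match or a == b):
            mapping[si] = pi
        if a != "-":
            pi += 1
        if b != "-":
            si += 1
    out = features[features[residue_col].isin(mapping)].copy()
    unmapped = len(features) - len(out)
    out["codon_index"] = out[residue_col].map(mapping)
    out.attrs["n_unmapped"] = unmapped
    if len(out) == 0:
        warnings.warn("no residues could be mapped onto the alignment")
    return out


def grantham_class(
    aa_from: str,
    aa_to: str,
    volume_cutoff: Optional[float] = None,
    polarity_cutoff: Optional[float] = None,
) -> str:
    """Conservative vs radical amino-acid change by Grantham indices.

    A change is radical iff the absolute difference in either the volume
    or the polarity index exceeds its cutoff.  Default cutoffs are the
    midpoint of each index's range over the 20 standard residues; the
    classification is symmetric in its arguments.
    """
    aa_from, aa_to = aa_from.upper(), aa_to.upper()
    for aa in (aa_from, aa_to):
        if aa not in GRANTHAM_VOLUME:
            raise KeyError(f"nonstandard amino acid {aa!r}")
    if volume_cutoff is None:
        v = np.array(list(GRANTHAM_VOLUME.values()))
        volume_cutoff = (v.max() - v.min()) / 2.0
    if polarity_cutoff is None:
        p = np.array(list(GRANTHAM_POLARITY.values()))
        polarity_cutoff = (p.max() - p.min()) / 2.0
    dv = abs(GRANTHAM_VOLUME[aa_from] - GRANTHAM_VOLUME[aa_to])
    dp = abs(GRANTHAM_POLARITY[aa_from] - GRANTHAM_POLARITY[aa_to])
    return "radical" if (dv > volume_cutoff or dp > polarity_cutoff) else "conservative"


def category_spectra(
    assignment: CategoryAssignment,
    spectra: Mapping,
) -> dict[str, SpectrumSet]:
    """Pool per-unit spectra into one spectrum per category label.

    Units lacking a spectrum are excluded with a warning; categories with
    no remaining unit are dropped.
    """
    missing = [u for u in assignment.membership.index if u not in spectra]
    if missing:
        warnings.warn(
            f"{assignment.scheme_name}: {len(missing)} units without a "
            "spectrum were excluded"
        )
    out: dict[str, SpectrumSet] = {}
    for label, units in assignment.units_by_label().items():
        have = [spectra[u] for u in units if u in spectra]
        if have:
            out[label] = aggregate_spectra(have, name=label)
    return out
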