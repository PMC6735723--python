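"""Site frequency spectrum containers and their on-disk dialects.

The unit consumed by every DFE fit is a :class:`SpectrumSet`: synonymous and
nonsynonymous unfolded (or folded) site frequency spectra together with the
fractional site opportunities (Ls, Ln) and the fixed-difference counts
(Ds, Dn) against the outgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "fold_spectrum",
    "aggregate_spectra",
    "to_dofe_line",
    "from_dofe_line",
    "write_spectra_tsv",
    "read_spectra_tsv",
]


@dataclass
class SpectrumSet:
    """Synonymous/nonsynonymous SFS plus site and divergence counts.

    Parameters
    ----------
    n : int
        Sample size in chromosomes. SFS vectors have length ``n - 1``;
        entry ``i - 1`` counts sites with ``i`` derived copies.
    Ls, Ln : float
        Synonymous and nonsynonymous site opportunities (fractional sites).
    sfs_syn, sfs_nonsyn : array-like
        Polymorphic site counts per derived-allele class ``1 .. n-1``.
    Ds, Dn : float
        Synonymous and nonsynonymous fixed differences vs. the outgroup.
    folded : bool
        If True, entries above ``floor(n/2)`` are zero and classes ``i`` and
        ``n - i`` have been pooled.
    """

    n: int
    Ls: float
    Ln: float
    sfs_syn: np.ndarray
    sfs_nonsyn: np.ndarray
    Ds: float = 0.0
    Dn: float = 0.0
    folded: bool = False
    name: str = "spectrum"

    def __post_init__(self) -> None:
        self.sfs_syn = np.asarray(self.sfs_syn, dtype=float)
        self.sfs_nonsyn = np.asarray(self.sfs_nonsyn, dtype=float)
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        for v, lab in ((self.sfs_syn, "sfs_syn"), (self.sfs_nonsyn, "sfs_nonsyn")):
            if v.shape != (self.n - 1,):
                raise ValueError(
                    f"{lab} must have length n-1={self.n - 1}, got {v.shape}"
                )
            if np.any(v < 0):
                raise ValueError(f"{lab} has negative entries")
        if self.Ls < 0 or self.Ln < 0 or self.Ds < 0 or self.Dn < 0:
            raise ValueError("Ls, Ln, Ds, Dn must be non-negative")
        if self.folded:
            half = self.n // 2
            if np.any(self.sfs_syn[half:] != 0) or np.any(self.sfs_nonsyn[half:] != 0):
                raise ValueError("folded spectrum has mass above floor(n/2)")

    # -- convenience -------------------------------------------------------

    @property
    def classes(self) -> np.ndarray:
        """Derived-count classes 1..n-1."""
        return np.arange(1, self.n)

    def total_polymorphisms(self) -> float:
        return float(self.sfs_syn.sum() + self.sfs_nonsyn.sum())

    def copy(self, **changes) -> "SpectrumSet":
        out = replace(self, **changes)
        out.sfs_syn = out.sfs_syn.copy()
        out.sfs_nonsyn = out.sfs_nonsyn.copy()
        return out


def fold_spectrum(s: SpectrumSet) -> SpectrumSet:
    """Fold an unfolded spectrum: ``f_i = u_i + u_{n-i}`` for ``i < n/2``.

    When ``n`` is even the central class ``n/2`` maps to itself.  Folding
    conserves the total number of polymorphic sites.
    """
    if s.folded:
        raise ValueError("spectrum is already folded")
    n = s.n

    def _fold(u: np.ndarray) -> np.ndarray:
        f = np.zeros_like(u)
        for i in range(1, n):
            j = min(i, n - i)
            f[j - 1] += u[i - 1]
        return f

    return SpectrumSet(
        n=n,
        Ls=s.Ls,
        Ln=s.Ln,
        sfs_syn=_fold(s.sfs_syn),
        sfs_nonsyn=_fold(s.sfs_nonsyn),
        Ds=s.Ds,
        Dn=s.Dn,
        folded=True,
        name=s.name,
    )


def aggregate_spectra(spectra: Sequence[SpectrumSet], name: str = "pooled") -> SpectrumSet:
    """Element-wise sum of spectra sharing the same ``n`` and folding."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot aggregate an empty list of spectra")
    first = spectra[0]
    for s in spectra[1:]:
        if s.n != first.n:
            raise ValueError(f"mismatched sample sizes: {s.n} != {first.n}")
        if s.folded != first.folded:
            raise ValueError("cannot mix folded and unfolded spectra")
    return SpectrumSet(
        n=first.n,
        Ls=float(sum(s.Ls for s in spectra)),
        Ln=float(sum(s.Ln for s in spectra)),
        sfs_syn=np.sum([s.sfs_syn for s in spectra], axis=0),
        sfs_nonsyn=np.sum([s.sfs_nonsyn for s in spectra], axis=0),
        Ds=float(sum(s.Ds for s in spectra)),
        Dn=float(sum(s.Dn for s in spectra)),
        folded=first.folded,
        name=name,
    )


# ---------------------------------------------------------------------------
# On-disk dialects
# ---------------------------------------------------------------------------

def to_dofe_line(s: SpectrumSet, fmt: str = "%.6g") -> str:
    """Serialize one spectrum as a single tab-separated line.

    Field order (bit-exact contract, tab-separated)::

        name  n  Ln  x_1 ... x_{n-1}  Ls  s_1 ... s_{n-1}  Ln  Dn  Ls  Ds

    where ``x_i``/``s_i`` are the nonsynonymous/synonymous SFS entries for
    derived-count class ``i``.  ``Ln``/``Ls`` appear twice (once heading the
    SFS block, once heading the divergence block) following the one-line
    layout used by DoFE/Grapes-style inputs.  Numbers are rendered with
    ``fmt`` (default ``%.6g``).
    """
    parts: list[str] = [s.name, str(s.n), fmt % s.Ln]
    parts += [fmt % v for v in s.sfs_nonsyn]
    parts.append(fmt % s.Ls)
    parts += [fmt % v for v in s.sfs_syn]
    parts += [fmt % s.Ln, fmt % s.Dn, fmt % s.Ls, fmt % s.Ds]
    return "\t".join(parts)


def from_dofe_line(line: str, folded: bool = False) -> SpectrumSet:
    """Parse the one-line dialect written by :func:`to_dofe_line`."""
    parts = line.rstrip("\n").split("\t")
    name = parts[0]
    n = int(parts[1])
    vals = [float(v) for v in parts[2:]]
    if len(vals) != 2 * (n - 1) + 6:
        raise ValueError(
            f"malformed SFS line for {name!r}: expected {2 * (n - 1) + 6} numeric "
            f"fields for n={n}, got {len(vals)}"
        )
    Ln = vals[0]
    sfs_nonsyn = vals[1 : n]
    Ls = vals[n]
    sfs_syn = vals[n + 1 : 2 * n]
    Ln2, Dn, Ls2, Ds = vals[2 * n : 2 * n + 4]
    if not (np.isclose(Ln, Ln2) and np.isclose(Ls, Ls2)):
        warnings.warn(f"inconsistent duplicated Ls/Ln fields in SFS line {name!r}")
    return SpectrumSet(
        n=n, Ls=Ls, Ln=Ln, sfs_syn=sfs_syn, sfs_nonsyn=sfs_nonsyn,
        Ds=Ds, Dn=Dn, folded=folded, name=name,
    )


def _spectrum_frame(s: SpectrumSet) -> pd.DataFrame:
    rows = []
    for cls, sfs, L, D in (
        ("synonymous", s.sfs_syn, s.Ls, s.Ds),
        ("nonsynonymous", s.sfs_nonsyn, s.Ln, s.Dn),
    ):
        rows.append(
            {"name": s.name, "class": cls, "n": s.n, "L": L, "D": D,
             "folded": s.folded,
             **{f"sfs_{i}": sfs[i - 1] for i in range(1, s.n)}}
        )
    return pd.DataFrame(rows)


def write_spectra_tsv(spectra: Iterable[SpectrumSet], path) -> None:
    """Write spectra as a TSV with one row per (spectrum, class)."""
    df = pd.concat([_spectrum_frame(s) for s in spectra], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)


def read_spectra_tsv(path) -> list[SpectrumSet]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for name, grp in df.groupby("name", sort=False):
        grp = grp.set_index("class")
        n = int(grp["n"].iloc[0])
        sfs_cols = [f"sfs_{i}" for i in range(1, n)]
        out.append(
            SpectrumSet(
                n=n,
                Ls=float(grp.loc["synonymous", "L"]),
                Ln=float(grp.loc["nonsynonymous", "L"]),
                sfs_syn=grp.loc["synonymous", sfs_cols].to_numpy(dtype=float),
                sfs_nonsyn=grp.loc["nonsynonymous", sfs_cols].to_numpy(dtype=float),
                Ds=float(grp.loc["synonymous", "D"]),
                Dn=float(grp.loc["nonsynonymous", "D"]),
                folded=bool(grp["folded"].iloc[0]),
                name=str(name),
            )
        )
    return out
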