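"""Pairwise host-use dissimilarity between herbivore species.

Two index families quantify how different the host repertoires of two
herbivores are:

* **jaccard** — set-based; counts shared and unique host species.
* **unifrac** — phylogeny-aware; replaces counts with shared and unique
  branch length on a host phylogeny, so using two closely related hosts is
  "almost the same" host use.

Either family's dissimilarity decomposes additively (Jaccard-family
partition) into a **turnover** component (host replacement) and a
**nestedness** component (one repertoire being a subset of a broader one):

    total     = (b + c) / (a + b + c)
    turnover  = 2·min(b, c) / (a + 2·min(b, c))
    nestedness = total − turnover

with a = shared (count or branch length), b/c = unique to either species.

Herbivores whose hosts fall outside the host phylogeny entirely can be
flagged as *override* taxa: every pair involving one is assigned maximum
turnover (1) and minimum nestedness (0) in both families, the conservative
convention for a taxon whose dietary distance to the rest is off the scale
of the reference tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import PhyloTree, normalize_label

__all__ = [
    "PairComponents",
    "HostUseMatrix",
    "jaccard_components",
    "unifrac_components",
    "partition",
    "dissimilarity_matrix",
    "FAMILIES",
    "COMPONENTS",
]

FAMILIES = ("jaccard", "unifrac")
COMPONENTS = ("total", "turnover", "nestedness")


@dataclass(frozen=True)
class PairComponents:
    """Shared/unique components (a, b, c) for one pair of host sets.

    For family="jaccard" these are set cardinalities; for family="unifrac"
    they are branch-length sums on the host tree.
    """

    a: float
    b: float
    c: float
    family: str

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("components must be non-negative")


class HostUseMatrix:
    """Binary herbivore × host incidence with optional override flags.

    Parameters
    ----------
    incidence:
        DataFrame with herbivore labels as the index, host labels as
        columns, entries 0/1.
    override:
        Optional boolean Series (aligned with the herbivore index) marking
        taxa whose hosts are not on the host tree; such rows may be empty
        and every pair involving them gets the fixed turnover-1/nestedness-0
        dissimilarity.
    """

    def __init__(self, incidence: pd.DataFrame, override: pd.Series | None = None):
        inc = incidence.copy()
        inc.index = [normalize_label(i) for i in inc.index]
        inc.columns = [normalize_label(c) for c in inc.columns]
        if inc.index.has_duplicates:
            dups = sorted(set(inc.index[inc.index.duplicated()]))
            raise ValueError(f"duplicate herbivore labels: {', '.join(dups)}")
        if inc.columns.has_duplicates:
            dups = sorted(set(inc.columns[inc.columns.duplicated()]))
            raise ValueError(f"duplicate host labels: {', '.join(dups)}")
        vals = inc.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary entry {vals[r, c]!r} at row {inc.index[r]!r}, "
                f"column {inc.columns[c]!r}"
            )
        self.incidence = inc.astype(np.int8)
        if override is None:
            override = pd.Series(False, index=inc.index)
        else:
            override = override.reindex(inc.index).fillna(False).astype(bool)
        self.override = override
        empties = [
            lab
            for lab in inc.index
            if self.incidence.loc[lab].sum() == 0 and not override[lab]
        ]
        if empties:
            raise ValueError(
                "herbivore rows with no hosts and no override flag: "
                + ", ".join(empties)
            )

    # -- convenience ----------------------------------------------------------

    @property
    def herbivores(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def hosts(self) -> list[str]:
        return list(self.incidence.columns)

    @property
    def n_herbivores(self) -> int:
        return len(self.incidence.index)

    def host_set(self, herbivore: str) -> frozenset[str]:
        row = self.incidence.loc[normalize_label(herbivore)]
        return frozenset(row.index[row == 1])

    def breadths(self) -> pd.Series:
        """Hosts per herbivore (host breadth)."""
        return self.incidence.sum(axis=1).astype(int)

    def subset(self, herbivores: list[str]) -> "HostUseMatrix":
        labs = [normalize_label(h) for h in herbivores]
        missing = [l for l in labs if l not in self.incidence.index]
        if missing:
            raise KeyError(f"unknown herbivores: {', '.join(missing)}")
        return HostUseMatrix(self.incidence.loc[labs], self.override.loc[labs])

    def validate_against_tree(self, host_tree: PhyloTree) -> None:
        """Every host used by a non-override herbivore must be a tree tip."""
        tips = set(host_tree.tip_labels)
        used = self.incidence.loc[~self.override]
        used_hosts = set(used.columns[(used.sum(axis=0) > 0)])
        missing = sorted(used_hosts - tips)
        if missing:
            raise ValueError(
                "hosts used by non-override herbivores but absent from the "
                "host tree: " + ", ".join(missing)
            )

    # -- I/O -------------------------------------------------------------------

    @classmethod
    def from_delimited(cls, source, sep: str | None = None) -> "HostUseMatrix":
        """Read from CSV/TSV text: first column herbivore labels, header row
        host labels, entries 0/1; optional ``off_tree`` column ∈ {0,1} sets
        the override flag."""
        if isinstance(source, (str, bytes)) and "\n" in str(source):
            source = io.StringIO(source)
        df = pd.read_csv(source, sep=sep, engine="python", index_col=0)
        override = None
        if "off_tree" in df.columns:
            flags = df.pop("off_tree")
            bad = ~flags.isin((0, 1))
            if bad.any():
                raise ValueError(
                    f"off_tree column must be 0/1; bad rows: "
                    f"{', '.join(map(str, df.index[bad]))}"
                )
            override = flags.astype(bool)
        return cls(df, override)

    def to_delimited(self, path, sep: str = ",") -> None:
        out = self.incidence.copy()
        if self.override.any():
            out["off_tree"] = self.override.astype(int)
        out.to_csv(path, sep=sep)


# -- pairwise components -------------------------------------------------------


def jaccard_components(set1: frozenset | set, set2: frozenset | set) -> PairComponents:
    """Shared / unique host counts for two non-empty host sets."""
    if not set1 or not set2:
        raise ValueError("host sets must be non-empty")
    s1, s2 = set(set1), set(set2)
    return PairComponents(
        a=len(s1 & s2), b=len(s1 - s2), c=len(s2 - s1), family="jaccard"
    )


def unifrac_components(
    host_tree: PhyloTree, set1: frozenset | set, set2: frozenset | set
) -> PairComponents:
    """Shared / unique branch length on ``host_tree`` for two host sets.

    a is the total length of branches covered by both sets, b/c the length
    covered by only one.  On a star tree with unit branches these equal the
    Jaccard counts exactly.
    """
    if not set1 or not set2:
        raise ValueError("host sets must be non-empty")
    cov1 = host_tree.coverage_vector(set(set1))
    cov2 = host_tree.coverage_vector(set(set2))
    L = host_tree.branch_lengths
    return PairComponents(
        a=float(L[cov1 & cov2].sum()),
        b=float(L[cov1 & ~cov2].sum()),
        c=float(L[cov2 & ~cov1].sum()),
        family="unifrac",
    )


def partition(components: PairComponents) -> tuple[float, float, float]:
    """Jaccard-family partition of (a, b, c) into (total, turnover, nestedness).

    total = (b+c)/(a+b+c); turnover = 2·min(b,c)/(a+2·min(b,c));
    nestedness = total − turnover.  All three lie in [0, 1] and
    total = turnover + nestedness by construction.
    """
    a, b, c = components.a, components.b, components.c
    denom = a + b + c
    if denom <= 0:
        raise ValueError("a + b + c must be positive (empty host sets upstream?)")
    total = (b + c) / denom
    m = min(b, c)
    turnover = 0.0 if m == 0 else 2.0 * m / (a + 2.0 * m)
    return total, turnover, total - turnover


# -- full matrices --------------------------------------------------------------


def _component_arrays(
    matrix: HostUseMatrix, host_tree: PhyloTree | None, family: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(a, b, c) arrays for every herbivore pair, vectorized.

    Override rows participate with whatever incidence they carry (possibly
    empty); their entries are replaced by the fixed override values by the
    caller, so garbage in these positions is harmless.
    """
    B = matrix.incidence.to_numpy(dtype=float)
    if family == "jaccard":
        shared = B @ B.T
        sizes = B.sum(axis=1)
    elif family == "unifrac":
        if host_tree is None:
            raise ValueError("family='unifrac' requires a host tree")
        # coverage per herbivore: which host-tree branches its host set spans
        col_of = {lab: j for j, lab in enumerate(matrix.hosts)}
        tips_on_tree = [lab for lab in matrix.hosts if lab in host_tree._tip_index]
        sel = np.zeros((len(matrix.hosts), host_tree.n_tips))
        for lab in tips_on_tree:
            sel[col_of[lab], host_tree._tip_index[lab]] = 1.0
        cov = (B @ sel) @ host_tree._branch_tip_mask.T.astype(float) > 0
        L = host_tree.branch_lengths
        shared = (cov * L) @ cov.T
        sizes = cov @ L
    else:
        raise ValueError(f"unknown family {family!r}")
    a = shared
    b = sizes[:, None] - shared
    c = sizes[None, :] - shared
    return a, b, c


def dissimilarity_matrix(
    matrix: HostUseMatrix,
    host_tree: PhyloTree | None = None,
    family: str = "jaccard",
    component: str = "total",
) -> pd.DataFrame:
    """Symmetric herbivore × herbivore dissimilarity for one family/component.

    Entries lie in [0, 1]; the diagonal is 0; pairs involving an
    override-flagged herbivore get turnover 1, nestedness 0, total 1.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if family == "unifrac":
        if host_tree is None:
            raise ValueError("family='unifrac' requires a host tree")
        matrix.validate_against_tree(host_tree)

    a, b, c = _component_arrays(matrix, host_tree, family)
    denom = a + b + c
    ov = matrix.override.to_numpy(dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        total = np.where(denom > 0, (b + c) / denom, 0.0)
        m = np.minimum(b, c)
        turnover = np.where(m > 0, 2.0 * m / (a + 2.0 * m), 0.0)
    nestedness = total - turnover

    pair_ov = ov[:, None] | ov[None, :]
    total = np.where(pair_ov, 1.0, total)
    turnover = np.where(pair_ov, 1.0, turnover)
    nestedness = np.where(pair_ov, 0.0, nestedness)

    out = {"total": total, "turnover": turnover, "nestedness": nestedness}[component]
    out = np.asarray(out, dtype=float).copy()
    np.fill_diagonal(out, 0.0)
    out = (out + out.T) / 2.0  # symmetrize away float noise
    labs = matrix.herbivores
    df = pd.DataFrame(out, index=labs, columns=labs)
    df.attrs["family"] = family
    df.attrs["component"] = component
    return df
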