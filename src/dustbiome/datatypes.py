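"""Core in-memory containers for the coupled geochemistry/microbiome pipeline.

All concentrations are held in fixed internal units: element concentrations
in ng/m^3, gravimetric PM masses in µg/m^3, and source profile entries as
dimensionless mass fractions.  Converters live at the IO boundary so that a
silent factor-of-1000 error cannot propagate through the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode


class ValidationError(ValueError):
    """Raised when an input table or tree violates a structural invariant."""


@dataclass
class ElementPanel:
    """Per-sample element concentrations with 1-sigma uncertainties.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample labels (e.g. ``S1`` .. ``S9``).
    element_names : list of str
        Chemical symbols for the columns of `conc` / `unc`.
    conc : ndarray of shape (n_samples, n_elements)
        Concentrations, ng/m^3.  NaN marks a missing measurement.
    unc : ndarray of shape (n_samples, n_elements)
        Matching 1-sigma uncertainties, ng/m^3; must be > 0 wherever the
        concentration is present.
    pm10_mass, pm25_mass : ndarray of shape (n_samples,), optional
        Gravimetric masses, µg/m^3.
    start_dates, end_dates : list, optional
        Calendar dates; retained as metadata, never used in computation.
    """

    sample_ids: list
    element_names: list
    conc: np.ndarray
    unc: np.ndarray
    pm10_mass: np.ndarray | None = None
    pm25_mass: np.ndarray | None = None
    start_dates: list | None = None
    end_dates: list | None = None

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.unc = np.asarray(self.unc, dtype=float)
        n, p = len(self.sample_ids), len(self.element_names)
        if self.conc.shape != (n, p):
            raise ValidationError(
                f"conc shape {self.conc.shape} does not match "
                f"({n} samples, {p} elements)"
            )
        if self.unc.shape != self.conc.shape:
            raise ValidationError("conc and unc must have identical shape")
        present = ~np.isnan(self.conc)
        if np.any(self.conc[present] < 0):
            i, j = np.argwhere(present & (self.conc < 0))[0]
            raise ValidationError(
                f"negative concentration at sample {self.sample_ids[i]!r}, "
                f"element {self.element_names[j]!r}"
            )
        if np.any(self.unc[present] <= 0):
            i, j = np.argwhere(present & ~(self.unc > 0))[0]
            raise ValidationError(
                f"non-positive uncertainty at sample {self.sample_ids[i]!r}, "
                f"element {self.element_names[j]!r}"
            )
        if self.pm10_mass is not None:
            self.pm10_mass = np.asarray(self.pm10_mass, dtype=float)
            if np.any(~np.isnan(self.pm10_mass) & (self.pm10_mass <= 0)):
                raise ValidationError("pm10_mass must be > 0")
        if self.pm25_mass is not None:
            self.pm25_mass = np.asarray(self.pm25_mass, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def element_index(self, names) -> np.ndarray:
        missing = [e for e in names if e not in self.element_names]
        if missing:
            raise KeyError(f"elements not in panel: {missing}")
        return np.array([self.element_names.index(e) for e in names])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.conc, index=self.sample_ids, columns=self.element_names)


@dataclass
class SourceProfileSet:
    """Aerosol source profiles: element mass fractions per unit source mass."""

    source_names: list
    element_names: list
    frac: np.ndarray
    frac_unc: np.ndarray

    def __post_init__(self):
        self.frac = np.asarray(self.frac, dtype=float)
        self.frac_unc = np.asarray(self.frac_unc, dtype=float)
        k, p = len(self.source_names), len(self.element_names)
        if self.frac.shape != (k, p):
            raise ValidationError(
                f"frac shape {self.frac.shape} does not match "
                f"({k} sources, {p} elements)"
            )
        if self.frac_unc.shape != self.frac.shape:
            raise ValidationError("frac and frac_unc must have identical shape")
        if np.any(self.frac < 0) or np.any(self.frac > 1):
            raise ValidationError("mass fractions must lie in [0, 1]")
        sums = self.frac.sum(axis=1)
        if np.any(sums > 1.2):
            bad = self.source_names[int(np.argmax(sums))]
            raise ValidationError(
                f"profile {bad!r} has fraction sum {sums.max():.3f} > 1.2"
            )
        if np.any(self.frac_unc < 0):
            raise ValidationError("frac_unc must be >= 0")

    @property
    def n_sources(self) -> int:
        return len(self.source_names)

    def subset_elements(self, names) -> "SourceProfileSet":
        idx = [self.element_names.index(e) for e in names]
        return SourceProfileSet(
            self.source_names, list(names), self.frac[:, idx], self.frac_unc[:, idx]
        )


@dataclass
class OtuTable:
    """OTU count matrix (OTUs x samples) with optional taxonomy lineages."""

    otu_ids: list
    sample_ids: list
    counts: np.ndarray
    taxonomy: list | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError("counts shape must be (n_otus, n_samples)")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            dupes = pd.Index(self.otu_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValidationError(f"duplicate otu_ids: {dupes[:5]}")
        if self.taxonomy is not None and len(self.taxonomy) != len(self.otu_ids):
            raise ValidationError("taxonomy must have one lineage per OTU")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized proportions; all-zero samples warn and stay zero."""
        depth = self.counts.sum(axis=0).astype(float)
        if np.any(depth == 0):
            warnings.warn("one or more samples have zero total counts")
            depth = np.where(depth == 0, 1.0, depth)
        return self.counts / depth

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths; tips map to OTU ids."""

    tree: TreeNode
    tip_names: list = field(init=False)

    def __post_init__(self):
        tips = [t.name for t in self.tree.tips()]
        if any(n is None for n in tips):
            raise ValidationError("all tips must be named")
        if len(set(tips)) != len(tips):
            dupes = sorted({n for n in tips if tips.count(n) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                raise ValidationError(f"missing branch length above {node.name!r}")
            if node.length < 0:
                raise ValidationError(f"negative branch length above {node.name!r}")
        self.tip_names = tips

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def depths(self) -> dict:
        """Root-to-tip path length for every tip."""
        out = {}
        for tip in self.tree.tips():
            d = 0.0
            node = tip
            while node.parent is not None:
                d += node.length
                node = node.parent
            out[tip.name] = d
        return out

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        d = np.array(list(self.depths().values()))
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-12))


@dataclass
class CovariateTable:
    """Per-sample covariates: element concentrations or source contributions.

    `kind` distinguishes the two covariate classes the correlation screen
    reports separately ("element" vs "source").
    """

    sample_ids: list
    covariate_names: list
    values: np.ndarray
    kind: str = "element"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.covariate_names)):
            raise ValidationError("values shape must be (n_samples, n_covariates)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.covariate_names
        )
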