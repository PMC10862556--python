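"""Synthetic-data generators with known ground truth.

Every input class of the pipeline can be emulated at desk scale: linear
source mixtures with multiplicative noise (element panels), log-normally
distributed OTU abundances a subset of which co-vary linearly with a
covariate, Yule trees with lambda-scaled Brownian traits, and communities
whose compositional turnover decays exponentially along a gradient.  Each
generator is deterministic given (parameters, seed) and returns a
`SynthTruth` sidecar recording the ground truth it embedded.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .datatypes import CovariateTable, ElementPanel, OtuTable, Phylogeny, SourceProfileSet
from .io import read_newick

DEFAULT_SOURCES = (
    "African dust",
    "local soil",
    "concrete dust",
    "road dust",
    "motor vehicles",
    "sea salt",
    "oil combustion",
)

#: ~45-element panel mirroring a typical ICP-MS aerosol element list.
DEFAULT_ELEMENTS = (
    "Na Mg Al Si P S K Ca Ti V Cr Mn Fe Co Ni Cu Zn Ga As Se Rb Sr Y Zr Nb "
    "Mo Cd Sn Sb Cs Ba La Ce Pr Nd Sm Eu Gd Tb Dy Ho Er Yb Pb Th"
).split()

# characteristic (element, mass fraction) anchors per source
_SOURCE_SIGNATURES = {
    # Saharan mineral dust: the five crustal oxides close to ~1 of the mass
    "African dust": {"Si": 0.31, "Al": 0.095, "Ca": 0.045, "Fe": 0.051,
                     "Ti": 0.0055, "K": 0.020, "Mg": 0.013, "Na": 0.008,
                     "La": 3.5e-5, "Ce": 7.0e-5, "V": 1.0e-4, "Ni": 5.0e-5},
    "local soil": {"Si": 0.30, "Al": 0.065, "Ca": 0.022, "Fe": 0.030,
                   "Ti": 0.0035, "K": 0.015, "Mg": 0.009, "La": 2.8e-5,
                   "Ce": 5.8e-5},
    "concrete dust": {"Ca": 0.28, "Si": 0.10, "Al": 0.020, "Fe": 0.012,
                      "Mg": 0.006, "K": 0.004, "S": 0.006},
    "road dust": {"Si": 0.18, "Ca": 0.09, "Al": 0.045, "Fe": 0.06,
                  "Zn": 0.0012, "Cu": 4.0e-4, "Ba": 6.0e-4, "Pb": 1.5e-4},
    "motor vehicles": {"Fe": 0.05, "Zn": 0.008, "Cu": 0.004, "Ba": 0.003,
                       "Pb": 0.0012, "Mn": 8.0e-4, "Ca": 0.02, "S": 0.015},
    "sea salt": {"Na": 0.31, "Mg": 0.037, "S": 0.026, "Ca": 0.012, "K": 0.011,
                 "Sr": 2.3e-4},
    "oil combustion": {"V": 0.012, "Ni": 0.006, "S": 0.08, "Fe": 0.008,
                       "Zn": 0.0015, "La": 4.0e-6},
}


@dataclass
class SynthTruth:
    """Ground truth embedded by a generator run."""

    seed: int
    params: dict = field(default_factory=dict)
    source_contributions: list | None = None
    linked_otus: list | None = None
    effect_size: float | None = None
    lambda_true: float | None = None
    turnover_rate: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


# ---------------------------------------------------------------------------
# Element panels
# ---------------------------------------------------------------------------

def gen_profiles(
    n_sources: int = 7,
    elements=DEFAULT_ELEMENTS,
    seed: int = 0,
    max_condition: float = 100.0,
    unc_cv: float = 0.15,
) -> SourceProfileSet:
    """Well-conditioned synthetic source profile set.

    The first sources follow the default urban-plus-dust source mix: a
    crustal African-dust profile, local soil, concrete/cement, road dust,
    vehicles, sea salt, and a V/Ni-rich oil-combustion profile.  Trace
    elements not pinned by a signature get small random fractions.  Draws
    are rejected until the column-normalized condition number of the
    profile matrix is below `max_condition`.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    names = [DEFAULT_SOURCES[i] if i < len(DEFAULT_SOURCES) else f"source_{i + 1}"
             for i in range(n_sources)]
    elements = list(elements)
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        frac = np.zeros((n_sources, len(elements)))
        for i, name in enumerate(names):
            sig = _SOURCE_SIGNATURES.get(name, {})
            for j, e in enumerate(elements):
                if e in sig:
                    frac[i, j] = sig[e] * rng.lognormal(0.0, 0.10)
                else:
                    frac[i, j] = 10 ** rng.uniform(-7.0, -4.5)
        sums = frac.sum(axis=1, keepdims=True)
        over = sums > 1.0
        if np.any(over):
            frac = np.where(over, frac / (sums * 1.05), frac)
        F = frac.T
        cond = np.linalg.cond(F / np.linalg.norm(F, axis=0))
        if cond < max_condition:
            return SourceProfileSet(names, elements, frac, unc_cv * frac)
    raise RuntimeError(
        f"could not draw a profile set with condition number < {max_condition} "
        "in 1000 attempts"
    )


def gen_samples(
    profiles: SourceProfileSet,
    S_true: np.ndarray,
    noise_cv: float = 0.10,
    seed: int = 0,
    secondary_fraction: float = 0.18,
    sample_ids=None,
) -> tuple[ElementPanel, SynthTruth]:
    """Element panel from true contributions: C = F.S with lognormal noise.

    `S_true` is (n_samples, n_sources) in µg/m^3; concentrations come out
    in ng/m^3 with reported uncertainties max(noise_cv, 0.05) * C (the
    floor keeps uncertainties positive when simulating noise-free data).
    PM10 is the apportioned total inflated by `secondary_fraction` of
    unapportionable secondary mass.
    """
    S_true = np.atleast_2d(np.asarray(S_true, dtype=float))
    if np.any(S_true < 0):
        raise ValueError("S_true must be non-negative")
    n, k = S_true.shape
    if k != profiles.n_sources:
        raise ValueError("S_true columns must match the number of sources")
    rng = np.random.default_rng(seed)
    clean = S_true @ (profiles.frac * 1000.0)  # ng/m^3
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=clean.shape)
        conc = clean * noise
    else:
        conc = clean.copy()
    unc = np.maximum(noise_cv, 0.05) * np.maximum(conc, 1e-12)
    pm10 = S_true.sum(axis=1) / (1.0 - secondary_fraction)
    ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    panel = ElementPanel(
        sample_ids=ids,
        element_names=list(profiles.element_names),
        conc=conc,
        unc=unc,
        pm10_mass=pm10,
    )
    truth = SynthTruth(
        seed=seed,
        params={"noise_cv": noise_cv, "secondary_fraction": secondary_fraction},
        source_contributions=S_true.tolist(),
    )
    return panel, truth


# ---------------------------------------------------------------------------
# OTU tables with covariate-linked members
# ---------------------------------------------------------------------------

_PHYLA = ("Proteobacteria", "Actinobacteria", "Firmicutes", "Bacteroidetes",
          "Chloroflexi", "Cyanobacteria", "Acidobacteria")


def _lineages(n_otus, rng, kingdom="Bacteria"):
    out = []
    for i in range(n_otus):
        if rng.random() < 0.25:
            out.append(f"k__{kingdom};p__unclassified")
        else:
            p = _PHYLA[rng.integers(len(_PHYLA))]
            out.append(f"k__{kingdom};p__{p};c__;o__;f__;g__Genus{i % 40}")
    return out


def gen_otu_table(
    n_otus: int,
    n_samples: int,
    n_linked: int,
    covariate,
    effect_size: float = 0.8,
    depth: int = 30_000,
    seed: int = 0,
) -> tuple[OtuTable, SynthTruth]:
    """OTU counts where `n_linked` OTUs track a covariate linearly.

    Baseline expected abundances are log-normal; for linked OTUs the
    expected proportion is scaled by (1 + effect_size * z) with z the
    standardized covariate (factors floored at 0.05 to stay positive).
    Counts are multinomial at `depth` per sample.
    """
    if n_linked > n_otus:
        raise ValueError("n_linked must be <= n_otus")
    import warnings as _warnings

    if depth < n_otus:
        _warnings.warn("sequencing depth below the OTU count; many zeros expected")
    cov = np.asarray(covariate, dtype=float)
    if cov.shape != (n_samples,):
        raise ValueError("covariate must have one value per sample")
    rng = np.random.default_rng(seed)
    z = (cov - cov.mean()) / cov.std()
    base = rng.lognormal(0.0, 1.5, size=n_otus)
    linked = rng.choice(n_otus, size=n_linked, replace=False)
    counts = np.zeros((n_otus, n_samples), dtype=np.int64)
    for s in range(n_samples):
        w = base.copy()
        w[linked] *= np.maximum(1.0 + effect_size * z[s], 0.05)
        counts[:, s] = rng.multinomial(depth, w / w.sum())
    table = OtuTable(
        otu_ids=[f"OTU_{i + 1}" for i in range(n_otus)],
        sample_ids=[f"S{s + 1}" for s in range(n_samples)],
        counts=counts,
        taxonomy=_lineages(n_otus, rng),
    )
    truth = SynthTruth(
        seed=seed,
        params={"depth": depth, "n_otus": n_otus},
        linked_otus=[f"OTU_{i + 1}" for i in sorted(linked)],
        effect_size=effect_size,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Yule trees with lambda-scaled Brownian traits
# ---------------------------------------------------------------------------

def gen_yule_tree(n_tips: int, seed: int = 0, birth_rate: float = 1.0) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree with `n_tips` extant tips."""
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    py_rng = random.Random(int(seed))
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=py_rng,
    )
    # the simulator stops exactly at the n-th speciation, leaving two
    # zero-length sibling tips; observe the tree a random waiting time
    # later (Exp with total rate n*birth) so tip covariances stay
    # nonsingular and the tree remains ultrametric
    extra = py_rng.expovariate(birth_rate * n_tips)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += extra
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return read_newick(newick)


def gen_tree_and_traits(
    n_tips: int,
    lambda_true: float,
    rate: float = 1.0,
    seed: int = 0,
) -> tuple[Phylogeny, dict, SynthTruth]:
    """Yule tree plus tip traits drawn at a known Pagel's lambda.

    Traits are multivariate normal with covariance
    rate * lambda_transform(C, lambda_true), C the Brownian tip covariance.
    """
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must be in [0, 1]")
    from .phylosig import lambda_transform, phylo_covariance

    phy = gen_yule_tree(n_tips, seed=seed)
    C, order = phylo_covariance(phy)
    V = rate * lambda_transform(C, lambda_true)
    rng = np.random.default_rng(seed + 1)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n_tips))
    y = L @ rng.standard_normal(n_tips)
    truth = SynthTruth(
        seed=seed, params={"n_tips": n_tips, "rate": rate}, lambda_true=lambda_true
    )
    return phy, dict(zip(order, y)), truth


# ---------------------------------------------------------------------------
# Distance-decay communities
# ---------------------------------------------------------------------------

def gen_turnover_communities(
    n_sites: int,
    gradient,
    rate: float,
    noise: float = 0.05,
    seed: int = 0,
    n_species: int = 300,
    depth: int = 5000,
) -> tuple[OtuTable, SynthTruth]:
    """Communities whose Bray-Curtis turnover decays exponentially.

    Species membership evolves as a Markov replacement process along the
    sorted gradient: between consecutive sites a distance dg apart each
    species survives with probability exp(-rate * dg) and is otherwise
    replaced by a fresh species.  Shared-species mass between two sites a
    distance d apart is therefore exp(-rate * d) in expectation, giving
    expected Bray-Curtis ~= 1 - exp(-rate * d).  Surviving species keep
    their abundance up to multiplicative lognormal jitter of CV `noise`.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    g = np.asarray(gradient, dtype=float)
    if g.shape != (n_sites,):
        raise ValueError("gradient must have one value per site")
    rng = np.random.default_rng(seed)
    order = np.argsort(g)
    next_id = n_species
    species = list(range(n_species))
    weights = {i: rng.lognormal(0.0, 1.0) for i in species}
    site_comp = {}
    prev_g = None
    for s in order:
        if prev_g is not None:
            dg = g[s] - prev_g
            surv = np.exp(-rate * dg)
            new_species = []
            for sp in species:
                if rng.random() < surv:
                    new_species.append(sp)
                else:
                    weights[next_id] = rng.lognormal(0.0, 1.0)
                    new_species.append(next_id)
                    next_id += 1
            species = new_species
        prev_g = g[s]
        jitter = rng.lognormal(0.0, noise, size=len(species)) if noise > 0 else 1.0
        site_comp[s] = dict(zip(species, np.array([weights[sp] for sp in species]) * jitter))

    all_species = sorted({sp for comp in site_comp.values() for sp in comp})
    idx = {sp: i for i, sp in enumerate(all_species)}
    counts = np.zeros((len(all_species), n_sites), dtype=np.int64)
    for s in range(n_sites):
        w = np.zeros(len(all_species))
        for sp, wt in site_comp[s].items():
            w[idx[sp]] += wt
        counts[:, s] = rng.multinomial(depth, w / w.sum())
    table = OtuTable(
        otu_ids=[f"SP_{sp}" for sp in all_species],
        sample_ids=[f"S{s + 1}" for s in range(n_sites)],
        counts=counts,
    )
    truth = SynthTruth(
        seed=seed,
        params={"n_sites": n_sites, "noise": noise, "n_species": n_species,
                "depth": depth, "gradient": g.tolist()},
        turnover_rate=rate,
    )
    return table, truth


def estimate_decay_rate(dissimilarity, gradient) -> dict:
    """Fit the distance-decay model d = 1 - (1 - b) exp(-rate * dg).

    The nugget b absorbs the dissimilarity floor that finite sequencing
    depth and abundance jitter impose at zero gradient distance, so `rate`
    estimates the compositional turnover rate itself.  `dissimilarity` is
    a DissimilarityMatrix (or square array) and `gradient` the per-site
    gradient values in matching order.
    """
    from scipy.optimize import curve_fit

    D = dissimilarity.matrix if hasattr(dissimilarity, "matrix") else np.asarray(dissimilarity)
    g = np.asarray(gradient, dtype=float)
    iu = np.triu_indices(len(g), k=1)
    dg = np.abs(g[iu[0]] - g[iu[1]])
    popt, _ = curve_fit(
        lambda x, r, b: 1.0 - (1.0 - b) * np.exp(-r * x),
        dg,
        D[iu],
        p0=[1.0, 0.05],
        bounds=([0.0, 0.0], [50.0, 1.0]),
    )
    return {"rate": float(popt[0]), "nugget": float(popt[1])}


# ---------------------------------------------------------------------------
# The demo scenario
# ---------------------------------------------------------------------------

#: Dust-pulse contribution trajectory (µg/m^3) shaped like the campaign's
#: low -> peak -> low apportioned-dust column.
DUST_TRAJECTORY = np.array([3.2, 24.8, 65.7, 54.3, 42.5, 12.0, 2.0, 14.0, 2.1])


def houston9(seed: int = 0) -> dict:
    """The default demo scenario: 9 samples, 7 sources, two communities.

    Mimics the shape of the study (one dust pulse, 848 bacterial and 1345
    fungal OTUs, trees for signal analysis).  Used for demos and the
    qualitative end-to-end checks, never for quantitative acceptance
    numbers.
    """
    rng = np.random.default_rng(seed)
    profiles = gen_profiles(7, seed=seed)
    n = 9
    S_true = np.column_stack([
        DUST_TRAJECTORY,
        rng.uniform(3, 10, n),        # local soil
        rng.uniform(5, 20, n),        # concrete dust
        rng.uniform(2, 8, n),         # road dust
        rng.uniform(5, 15, n),        # motor vehicles
        rng.uniform(1, 5, n),         # sea salt
        rng.uniform(0.2, 1.5, n),     # oil combustion
    ])
    panel, panel_truth = gen_samples(profiles, S_true, noise_cv=0.10, seed=seed + 1)
    bact, bact_truth = gen_otu_table(
        848, n, 60, DUST_TRAJECTORY, effect_size=0.8, depth=30_000, seed=seed + 2
    )
    fung, fung_truth = gen_otu_table(
        1345, n, 90, DUST_TRAJECTORY, effect_size=0.8, depth=109_000, seed=seed + 3
    )
    def _tree_for(table, n_tips, s):
        # tip labels map onto the table's most abundant OTUs
        phy = gen_yule_tree(n_tips, seed=s)
        top = np.argsort(table.counts.sum(axis=1))[::-1][:n_tips]
        for tip, i in zip(phy.tree.tips(), top):
            tip.name = table.otu_ids[i]
        return Phylogeny(phy.tree)

    bact_tree = _tree_for(bact, 60, seed + 4)
    fung_tree = _tree_for(fung, 60, seed + 5)
    sources_cov = CovariateTable(
        sample_ids=list(panel.sample_ids),
        covariate_names=list(profiles.source_names),
        values=S_true,
        kind="source",
    )
    return {
        "profiles": profiles,
        "panel": panel,
        "S_true": S_true,
        "bacteria": bact,
        "fungi": fung,
        "bacteria_tree": bact_tree,
        "fungi_tree": fung_tree,
        "source_covariates": sources_cov,
        "truth": {
            "panel": panel_truth.to_dict(),
            "bacteria": bact_truth.to_dict(),
            "fungi": fung_truth.to_dict(),
        },
    }
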