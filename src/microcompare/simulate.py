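"""Synthetic two-cohort microbiome data with known ground truth.

The generator emulates the statistical structure of a tribal-vs-urban gut
16S study: two cohorts (default 75 TR / 80 UR samples) of Dirichlet-
multinomial counts over a shared component (enterotype) catalogue, with

* a planted *diversity gap* (one cohort's Dirichlet concentrations flattened
  toward uniformity, giving more even, richer communities),
* planted *core* features (target prevalence at a target mean relative
  abundance, via zero-inflation of the sample proportions),
* planted *differentially abundant* features (the feature's concentration
  multiplied by a fold change in the enriched cohort), and
* metadata covariates (age, BMI, sex, diet, region) where chosen covariates
  are rank-correlated with chosen features through a Gaussian copula.

Every draw is controlled by a single integer seed, so tables are
reproducible byte for byte.  Sequencing depth is drawn uniformly per sample
(default 10,000-60,000 reads) so rarefaction is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import AbundanceTable

__all__ = [
    "DirichletComponent",
    "PlantedCore",
    "PlantedEffect",
    "MetadataLink",
    "CohortSpec",
    "default_spec",
    "lognormal_component",
    "generate_cohorts",
    "diversity_gap_spec",
    "save_spec",
    "load_spec",
]

TRIBAL_REGIONS = ("Andhra", "Assam", "Manipur", "Sikkim")
URBAN_REGION = "Ahmedabad"

# a small pool of real gut lineages (domain..genus) cycled over features so
# that taxonomy-aware stages (collapse, clade rollups) are exercised
_GENUS_POOL = (
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Alloprevotella"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Roseburia"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Eubacterium"),
    ("Bacteria", "Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Dialister"),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Aeromonadales", "Succinivibrionaceae", "Succinivibrio"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia"),
    ("Bacteria", "Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Collinsella"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
)


@dataclass
class DirichletComponent:
    """One Dirichlet component (an 'enterotype'): concentrations alpha > 0."""

    alpha: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 1:
            raise ValueError("alpha must be a vector")
        if not (self.alpha > 0).all():
            raise ValueError("all Dirichlet concentrations must be strictly positive")


@dataclass(frozen=True)
class PlantedCore:
    """Force a feature to a target prevalence/abundance in a cohort (or both)."""

    feature: int
    prevalence: float
    mean_abundance: float
    cohort: str | None = None  # None = plant in every cohort


@dataclass(frozen=True)
class PlantedEffect:
    """Multiply a feature's concentration by ``fold`` in the enriched cohort."""

    feature: int
    cohort: str
    fold: float


@dataclass(frozen=True)
class MetadataLink:
    """Rank-correlate a covariate with a feature's relative abundance."""

    feature: int
    covariate: str  # "age" or "bmi"
    direction: str = "increasing"  # or "decreasing"
    rho: float = 0.5


@dataclass
class CohortSpec:
    """Full description of a two-cohort simulation."""

    n_samples: dict[str, int]
    n_features: int
    components: list[DirichletComponent]
    component_weights: dict[str, np.ndarray]
    depth_range: tuple[int, int] = (10_000, 60_000)
    planted_core: list[PlantedCore] = field(default_factory=list)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    metadata_links: list[MetadataLink] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.component_weights = {
            c: np.asarray(w, dtype=float) for c, w in self.component_weights.items()
        }
        self.validate()

    @property
    def cohorts(self) -> list[str]:
        return list(self.n_samples)

    def validate(self) -> None:
        for comp in self.components:
            if comp.alpha.shape != (self.n_features,):
                raise ValueError(
                    f"component {comp.label!r}: alpha has length {comp.alpha.size}, "
                    f"expected n_features={self.n_features}"
                )
        for cohort, w in self.component_weights.items():
            if cohort not in self.n_samples:
                raise ValueError(f"weights given for unknown cohort {cohort!r}")
            if w.shape != (len(self.components),):
                raise ValueError(f"cohort {cohort!r}: weight vector length mismatch")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
                raise ValueError(f"cohort {cohort!r}: weights must be a probability vector")
        for cohort in self.n_samples:
            if cohort not in self.component_weights:
                raise ValueError(f"cohort {cohort!r} has no component weights")
        for pc in self.planted_core:
            if not (0 <= pc.prevalence <= 1 and 0 < pc.mean_abundance < 1):
                raise ValueError("planted core prevalence/abundance must lie in [0,1]")
            if not 0 <= pc.feature < self.n_features:
                raise ValueError(f"planted core feature {pc.feature} out of range")
        for pe in self.planted_effects:
            if pe.fold <= 0:
                raise ValueError("fold changes must be > 0")
            if pe.cohort not in self.n_samples:
                raise ValueError(f"planted effect names unknown cohort {pe.cohort!r}")
            if not 0 <= pe.feature < self.n_features:
                raise ValueError(f"planted effect feature {pe.feature} out of range")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("invalid depth_range")


def lognormal_component(
    n_features: int,
    total_concentration: float = 40.0,
    sigma: float = 1.5,
    label: str = "",
    seed: int = 0,
) -> DirichletComponent:
    """A realistic skewed component: lognormal alphas scaled to a target sum.

    Gut communities are dominated by a handful of taxa with a long tail;
    lognormal concentrations with sigma ~ 1.5 reproduce that shape.  The
    total concentration (default 40) sets the sample-to-sample overdispersion
    typical of stool 16S data.
    """
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_features)
    alpha = raw * (total_concentration / raw.sum())
    return DirichletComponent(alpha=alpha, label=label or f"comp{seed}")


def default_spec(
    n_features: int = 300,
    n_tr: int = 75,
    n_ur: int = 80,
    seed: int = 0,
) -> CohortSpec:
    """Study-shaped default: 75 TR / 80 UR samples over one component each."""
    tr = lognormal_component(n_features, label="TR-base", seed=seed * 1000 + 1)
    ur = lognormal_component(n_features, label="UR-base", seed=seed * 1000 + 2)
    return CohortSpec(
        n_samples={"TR": n_tr, "UR": n_ur},
        n_features=n_features,
        components=[tr, ur],
        component_weights={"TR": np.array([1.0, 0.0]), "UR": np.array([0.0, 1.0])},
        seed=seed,
    )


def _default_taxonomy(n_features: int) -> dict[str, tuple[str, ...]]:
    tax = {}
    for i in range(n_features):
        lineage = _GENUS_POOL[i % len(_GENUS_POOL)]
        tax[f"OTU_{i + 1}"] = tuple(lineage) + (f"{lineage[-1]}_sp{i + 1}",)
    return tax


def _effective_alpha(spec: CohortSpec, cohort: str, comp: DirichletComponent) -> np.ndarray:
    alpha = comp.alpha.copy()
    for pe in spec.planted_effects:
        if pe.cohort == cohort:
            alpha[pe.feature] *= pe.fold
    return alpha


def generate_cohorts(spec: CohortSpec) -> tuple[AbundanceTable, pd.DataFrame]:
    """Draw the two-cohort count table and its sample metadata.

    Per sample: a component is drawn from the cohort's mixture weights,
    proportions from Dirichlet(effective alpha), planted-core features are
    zeroed out with probability 1 - prevalence (then renormalized), the
    depth uniformly from ``depth_range``, and counts from a multinomial.
    Metadata covariates are drawn afterwards, re-ordered against feature
    abundances for the declared links.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    feature_ids = [f"OTU_{i + 1}" for i in range(spec.n_features)]
    lo, hi = spec.depth_range

    cols: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    component_of: list[int] = []
    for cohort in spec.cohorts:
        weights = spec.component_weights[cohort]
        alphas = [_effective_alpha(spec, cohort, comp) for comp in spec.components]
        plant = [
            pc for pc in spec.planted_core if pc.cohort is None or pc.cohort == cohort
        ]
        for s in range(spec.n_samples[cohort]):
            sid = f"{cohort}_{s + 1:03d}"
            k = int(rng.choice(len(weights), p=weights))
            component_of.append(k)
            props = rng.dirichlet(alphas[k])
            if plant:
                # implant cores directly: when present the feature sits in a
                # tight lognormal band around its target mean abundance, so
                # presence reliably clears detection-style thresholds
                planted_idx = [pc.feature for pc in plant]
                planted_vals = np.zeros(len(plant))
                for pi_, pc in enumerate(plant):
                    if rng.random() <= pc.prevalence:
                        sigma = 0.35
                        planted_vals[pi_] = rng.lognormal(
                            np.log(pc.mean_abundance) - sigma**2 / 2.0, sigma
                        )
                planted_total = planted_vals.sum()
                if planted_total >= 0.9:
                    raise ValueError("planted core abundances sum too close to 1")
                props[planted_idx] = 0.0
                rest = props.sum()
                if rest == 0:
                    raise ValueError("planted cores leave no mass for other features")
                props *= (1.0 - planted_total) / rest
                props[planted_idx] = planted_vals
            depth = int(rng.integers(lo, hi + 1))
            cols[sid] = rng.multinomial(depth, props)
            region = (
                URBAN_REGION
                if cohort == "UR"
                else TRIBAL_REGIONS[int(rng.integers(len(TRIBAL_REGIONS)))]
            )
            meta_rows.append(
                {
                    "sample_id": sid,
                    "cohort": cohort,
                    "region": region,
                    "sex": "male" if rng.random() < 0.5 else "female",
                    "diet": "vegetarian"
                    if rng.random() < (0.7 if cohort == "UR" else 0.3)
                    else "non-vegetarian",
                    "age": float(np.round(rng.uniform(18, 60), 1)),
                    "bmi": float(np.round(rng.uniform(15, 35), 1)),
                }
            )

    data = pd.DataFrame(cols, index=feature_ids)
    table = AbundanceTable(
        data=data, kind="counts", taxonomy=_default_taxonomy(spec.n_features)
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta["component"] = component_of

    rel = data.to_numpy(dtype=float) / data.to_numpy(dtype=float).sum(axis=0)
    for link in spec.metadata_links:
        _apply_link(meta, link, rel[link.feature], rng)
    return table, meta


def _apply_link(meta: pd.DataFrame, link: MetadataLink, abundance: np.ndarray, rng) -> None:
    """Reorder an existing covariate so its ranks track the feature's ranks.

    Gaussian copula: normal scores of the abundance ranks are mixed with
    independent noise at the requested rho, the covariate's sorted values are
    then assigned by the rank of the mixed scores.  ``direction="decreasing"``
    negates rho.
    """
    from scipy import stats

    if link.covariate not in meta.columns:
        raise ValueError(f"metadata link names unknown covariate {link.covariate!r}")
    rho = link.rho if link.direction == "increasing" else -link.rho
    n = len(abundance)
    # mid-rank normal scores; jitter breaks abundance ties (zeros) randomly
    r = stats.rankdata(abundance + rng.normal(0, 1e-12, n))
    z_feat = stats.norm.ppf(r / (n + 1))
    z = rho * z_feat + np.sqrt(1 - rho**2) * rng.normal(size=n)
    sorted_vals = np.sort(meta[link.covariate].to_numpy(dtype=float))
    meta[link.covariate] = sorted_vals[stats.rankdata(z).astype(int) - 1]


def diversity_gap_spec(
    base: CohortSpec, hi_cohort: str, concentration_scale: float
) -> CohortSpec:
    """Plant a diversity gap: flatten ``hi_cohort``'s components toward uniformity.

    Each concentration is raised to the power 1/scale (``alpha**(1/s)``), so
    skewed components become more even and richer -- higher Shannon, Simpson
    and richness -- while the other cohort is untouched.  ``scale=1`` is the
    identity, and applying scale ``a`` then ``b`` equals a single ``a*b``.
    """
    if hi_cohort not in base.n_samples:
        raise ValueError(f"unknown cohort {hi_cohort!r}")
    if concentration_scale < 1:
        raise ValueError("concentration_scale must be >= 1")
    if concentration_scale == 1:
        return base

    n_orig = len(base.components)
    flattened = [
        DirichletComponent(
            alpha=comp.alpha ** (1.0 / concentration_scale),
            label=f"{comp.label}|flat{concentration_scale:g}",
        )
        for comp in base.components
    ]
    components = list(base.components) + flattened
    weights = {}
    for cohort, w in base.component_weights.items():
        if cohort == hi_cohort:
            weights[cohort] = np.concatenate([np.zeros(n_orig), w])
        else:
            weights[cohort] = np.concatenate([w, np.zeros(n_orig)])
    return replace(base, components=components, component_weights=weights)


def active_alphas(spec: CohortSpec, cohort: str) -> list[np.ndarray]:
    """Alphas of the components a cohort actually uses (non-zero weight)."""
    w = spec.component_weights[cohort]
    return [spec.components[i].alpha for i in np.flatnonzero(w)]


# -- flat key=value spec serialization ----------------------------------


def save_spec(spec: CohortSpec, path) -> None:
    """Serialize a CohortSpec as a flat ``key = value`` config file."""
    lines = [
        f"n_features = {spec.n_features}",
        f"depth_min = {spec.depth_range[0]}",
        f"depth_max = {spec.depth_range[1]}",
        f"seed = {spec.seed}",
    ]
    for cohort in spec.cohorts:
        lines.append(f"cohort.{cohort}.n_samples = {spec.n_samples[cohort]}")
        w = ",".join(repr(float(x)) for x in spec.component_weights[cohort])
        lines.append(f"cohort.{cohort}.weights = {w}")
    for i, comp in enumerate(spec.components):
        lines.append(f"component.{i}.label = {comp.label}")
        lines.append(f"component.{i}.alpha = {','.join(repr(float(a)) for a in comp.alpha)}")
    for i, pc in enumerate(spec.planted_core):
        lines.append(
            f"core.{i} = {pc.feature},{pc.prevalence!r},{pc.mean_abundance!r},{pc.cohort or '*'}"
        )
    for i, pe in enumerate(spec.planted_effects):
        lines.append(f"effect.{i} = {pe.feature},{pe.cohort},{pe.fold!r}")
    for i, ml in enumerate(spec.metadata_links):
        lines.append(f"link.{i} = {ml.feature},{ml.covariate},{ml.direction},{ml.rho!r}")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_spec(path) -> CohortSpec:
    kv: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    n_features = int(kv["n_features"])
    cohorts = sorted(
        {k.split(".")[1] for k in kv if k.startswith("cohort.")},
        key=lambda c: list(kv).index(f"cohort.{c}.n_samples"),
    )
    components = []
    i = 0
    while f"component.{i}.alpha" in kv:
        components.append(
            DirichletComponent(
                alpha=np.array([float(x) for x in kv[f"component.{i}.alpha"].split(",")]),
                label=kv.get(f"component.{i}.label", f"comp{i}"),
            )
        )
        i += 1
    planted_core, planted_effects, links = [], [], []
    i = 0
    while f"core.{i}" in kv:
        f, p, m, c = kv[f"core.{i}"].split(",")
        planted_core.append(
            PlantedCore(int(f), float(p), float(m), None if c == "*" else c)
        )
        i += 1
    i = 0
    while f"effect.{i}" in kv:
        f, c, fold = kv[f"effect.{i}"].split(",")
        planted_effects.append(PlantedEffect(int(f), c, float(fold)))
        i += 1
    i = 0
    while f"link.{i}" in kv:
        f, cov, d, rho = kv[f"link.{i}"].split(",")
        links.append(MetadataLink(int(f), cov, d, float(rho)))
        i += 1
    return CohortSpec(
        n_samples={c: int(kv[f"cohort.{c}.n_samples"]) for c in cohorts},
        n_features=n_features,
        components=components,
        component_weights={
            c: np.array([float(x) for x in kv[f"cohort.{c}.weights"].split(",")])
            for c in cohorts
        },
        depth_range=(int(kv["depth_min"]), int(kv["depth_max"])),
        planted_core=planted_core,
        planted_effects=planted_effects,
        metadata_links=links,
        seed=int(kv["seed"]),
    )
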