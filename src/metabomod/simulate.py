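"""Synthetic cohorts and paired metabolome/proteome matrices with known truth.

The generator emulates the structure the analyses assume in real plasma
metabolomics: log-scale abundances, latent co-abundance modules, a handful of
group-shifted modules and singleton features, mild covariate confounding
(cases a few years older than controls), a location/scale batch shift applied
to the replication subsample only, and two annotation panels of global
metabolomics and complex-lipid size. Latent module scores are Laplace by
default: independent component analysis cannot separate purely Gaussian
latents (any rotation of them is an equally valid factorization), so a
heavy-tailed draw is required wherever ICA recovery is exercised.

Group effects are planted on the standardized scale: a module effect shifts
the module's latent score (unit variance) for cases, and a singleton effect
shifts the feature by ``effect x marginal SD`` so the standardized regression
coefficient recovered downstream is approximately the planted value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import Dataset

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_metabolome",
    "simulate_annotation",
    "simulate_proteome",
    "simulate_dataset",
]

CONDITION_FLAGS = ("gerd", "diabetes", "heart_disease", "hypertension")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the study design.

    Group sizes default to the 39/49 discovery and 17/19 replication split;
    panels default to 738 global-metabolomics-like (HD4) and 890
    complex-lipid-like (CLP) features (reducible for fast experiments). Three
    of the ten latent modules carry a +0.5 SD case shift on their latent
    score, and one complex-lipid feature carries a +0.74 SD standardized
    singleton effect — a hexosylceramide-scale effect.
    """

    seed: int = 0
    # cohort
    n_case_discovery: int = 39
    n_control_discovery: int = 49
    n_case_replication: int = 17
    n_control_replication: int = 19
    age_shift_years: float = 3.0
    fraction_caucasian: float = 0.87
    # metabolome panels
    n_features_hd4: int = 738
    n_features_clp: int = 890
    # latent module structure
    n_modules: int = 10
    module_size_range: tuple[int, int] = (10, 40)
    module_group_effect: tuple[float, ...] | None = None  # default: 3 x +0.5, rest 0
    singleton_effects: dict[str, float] | None = None  # default: first CLP feature +0.74
    latent_dist: str = "laplace"  # {"laplace", "normal", "t"}
    # nuisance structure
    covariate_loading_sd: float = 0.05
    batch_shift: float = 0.5
    batch_scale: float = 0.1
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    missing_rate: float = 0.0
    # annotation
    pathway_fidelity: float = 0.9
    decoy_pathway_size: int = 20
    # proteome
    n_proteins: int = 276
    n_protein_modules: int = 6
    protein_module_size_range: tuple[int, int] = (8, 20)
    n_shared_latents: int = 3
    latent_correlation: float = 0.8
    n_proteome_case: int = 30
    n_proteome_control: int = 66

    def __post_init__(self) -> None:
        if self.module_group_effect is None:
            eff = [0.5] * min(3, self.n_modules) + [0.0] * max(0, self.n_modules - 3)
            self.module_group_effect = tuple(eff)
        if len(self.module_group_effect) != self.n_modules:
            raise ValueError("module_group_effect length must equal n_modules")
        if self.singleton_effects is None:
            self.singleton_effects = {"CLP_0001": 0.74} if self.n_features_clp else {}
        if not -1.0 <= self.latent_correlation <= 1.0:
            raise ValueError("latent_correlation must lie in [-1, 1]")
        if self.module_size_range[0] < 2:
            raise ValueError("module sizes must be >= 2")
        if not 0.0 <= self.pathway_fidelity <= 1.0:
            raise ValueError("pathway_fidelity must lie in [0, 1]")
        for name in (
            "n_case_discovery",
            "n_control_discovery",
            "n_case_replication",
            "n_control_replication",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_samples(self) -> int:
        return (
            self.n_case_discovery
            + self.n_control_discovery
            + self.n_case_replication
            + self.n_control_replication
        )

    @property
    def n_features(self) -> int:
        return self.n_features_hd4 + self.n_features_clp

    def to_dict(self) -> dict:
        return asdict(self)

    def _streams(self) -> dict[str, np.random.Generator]:
        """Independent, deterministic substreams per generator stage."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("cohort", "metabolome", "proteome", "annotation")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the pipeline's output."""

    module_members: list[list[str]]
    latent_scores: pd.DataFrame  # samples x modules, post group shift
    affected_modules: list[int]
    differential_features: dict[str, float]  # feature -> planted standardized effect
    batch_params: pd.DataFrame  # per-feature location shift and scale factor
    module_pathways: list[str] = field(default_factory=list)
    shared_latents: dict[int, int] = field(default_factory=dict)  # protein -> metab module


def _draw_latents(rng: np.random.Generator, n: int, k: int, dist: str) -> np.ndarray:
    """Unit-variance latent scores; heavy tails keep ICA identifiable."""
    if dist == "laplace":
        return rng.laplace(scale=1 / np.sqrt(2), size=(n, k))
    if dist == "normal":
        return rng.standard_normal((n, k))
    if dist == "t":
        df = 5
        return rng.standard_t(df, size=(n, k)) / np.sqrt(df / (df - 2))
    raise ValueError(f"unknown latent_dist {dist!r}")


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a sample table honoring the symptom-score case/control definition.

    Cases receive checklist totals above 44 and controls below 22 by
    construction, cases average ``age_shift_years`` older, and the
    caucasian/other split follows ``fraction_caucasian``.
    """
    rng = config._streams()["cohort"]
    blocks = [
        ("discovery", "case", config.n_case_discovery),
        ("discovery", "control", config.n_control_discovery),
        ("replication", "case", config.n_case_replication),
        ("replication", "control", config.n_control_replication),
    ]
    rows = []
    i = 0
    for subsample, group, n in blocks:
        for _ in range(n):
            i += 1
            is_case = group == "case"
            age = rng.normal(52.8 + (config.age_shift_years if is_case else 0.0), 7.5)
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "group": group,
                    "age": float(np.clip(age, 30.0, 80.0)),
                    "race": "caucasian" if rng.random() < config.fraction_caucasian else "other",
                    "bmi": float(np.clip(rng.normal(31.0, 4.7), 18.0, 50.0)),
                    "subsample": subsample,
                    "pcl_total": int(rng.integers(45, 86) if is_case else rng.integers(17, 22)),
                    "gerd": bool(rng.random() < 0.30),
                    "diabetes": bool(rng.random() < 0.20),
                    "heart_disease": bool(rng.random() < 0.15),
                    "hypertension": bool(rng.random() < (0.45 if is_case else 0.28)),
                    "dust_exposure": int(rng.integers(0, 4)),
                }
            )
    if not rows:
        raise ValueError("cohort has zero samples; check group counts")
    return pd.DataFrame(rows).set_index("sample_id")


def _feature_ids(config: SimulationConfig) -> list[str]:
    hd4 = [f"HD4_{i + 1:04d}" for i in range(config.n_features_hd4)]
    clp = [f"CLP_{i + 1:04d}" for i in range(config.n_features_clp)]
    return hd4 + clp


def simulate_metabolome(
    config: SimulationConfig, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, GroundTruth]:
    """Metabolite matrix: baseline + module latents + effects + batch + noise.

    Module latent scores are shifted for cases on affected modules; the batch
    location/scale distortion hits replication samples only, scaling the
    noise term (the model empirical-Bayes batch adjustment assumes).
    """
    rng = config._streams()["metabolome"]
    n = len(cohort)
    feats = _feature_ids(config)
    p = len(feats)
    lo, hi = config.module_size_range
    if config.n_modules * hi > p:
        raise ValueError("module sizes exceed the number of features")

    # disjoint module memberships; singleton-effect features stay module-free
    # so a planted singleton is exactly a singleton
    reserved = {fidx for f, fidx in zip(feats, range(p)) if f in config.singleton_effects}
    pool = np.array([j for j in range(p) if j not in reserved])
    perm = pool[rng.permutation(len(pool))]
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    members: list[list[str]] = []
    start = 0
    for s in sizes:
        members.append(sorted(feats[j] for j in perm[start : start + s]))
        start += s

    is_case = (cohort["group"] == "case").to_numpy().astype(float)
    z = _draw_latents(rng, n, config.n_modules, config.latent_dist)
    for k, eff in enumerate(config.module_group_effect):
        z[:, k] += eff * is_case

    loadings = np.zeros((p, config.n_modules))
    fidx = {f: j for j, f in enumerate(feats)}
    for k, mem in enumerate(members):
        mag = rng.uniform(0.5, 1.0, size=len(mem))
        sign = rng.choice([-1.0, 1.0], size=len(mem))
        for f, l in zip(mem, mag * sign):
            loadings[fidx[f], k] = l

    age_l = rng.normal(0.0, config.covariate_loading_sd, size=p)
    bmi_l = rng.normal(0.0, config.covariate_loading_sd, size=p)
    age_std = (cohort["age"] - cohort["age"].mean()) / cohort["age"].std()
    bmi_std = (cohort["bmi"] - cohort["bmi"].mean()) / cohort["bmi"].std()

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    noise = rng.normal(0.0, config.noise_sd, size=(n, p))

    # batch (replication subsample): per-feature location shift, noise rescale
    gamma = rng.normal(config.batch_shift, abs(config.batch_shift) / 2 + 1e-12, size=p)
    delta = np.exp(rng.normal(0.0, config.batch_scale, size=p))
    in_rep = (cohort["subsample"] == "replication").to_numpy()
    noise[in_rep] = noise[in_rep] * delta

    values = (
        baseline
        + z @ loadings.T
        + np.outer(age_std, age_l)
        + np.outer(bmi_std, bmi_l)
        + noise
    )
    values[in_rep] += gamma

    # marginal SD per feature (pre group effect) for standardized singletons
    var_z = 1.0 + np.square(config.module_group_effect) * is_case.mean() * (1 - is_case.mean())
    sd = np.sqrt(
        (np.square(loadings) * var_z).sum(axis=1)
        + age_l**2
        + bmi_l**2
        + config.noise_sd**2
    )

    # plant singletons so the STANDARDIZED coefficient equals the requested
    # effect: the shift itself inflates the marginal SD by 1/sqrt(1 - e^2 pq)
    pq = is_case.mean() * (1 - is_case.mean())
    differential: dict[str, float] = {}
    for f, eff in config.singleton_effects.items():
        if f not in fidx:
            raise ValueError(f"singleton effect on unknown feature {f!r}")
        if eff**2 * pq >= 1.0:
            raise ValueError(f"singleton effect {eff} too large to standardize")
        j = fidx[f]
        values[:, j] += eff * sd[j] / np.sqrt(1 - eff**2 * pq) * is_case
        differential[f] = eff
    affected = [k for k, e in enumerate(config.module_group_effect) if e != 0.0]
    for k in affected:
        shift = config.module_group_effect[k]
        for f in members[k]:
            j = fidx[f]
            differential.setdefault(f, float(shift * loadings[j, k] / sd[j]))

    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        values = np.where(mask, np.nan, values)

    matrix = pd.DataFrame(values, index=cohort.index, columns=feats)
    truth = GroundTruth(
        module_members=members,
        latent_scores=pd.DataFrame(
            z, index=cohort.index, columns=[f"M{k + 1}" for k in range(config.n_modules)]
        ),
        affected_modules=affected,
        differential_features=differential,
        batch_params=pd.DataFrame({"shift": gamma, "scale": delta}, index=feats),
    )
    return matrix, truth


def simulate_annotation(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.Series]:
    """Panel + pathway annotation; planted modules map to dominant pathways.

    With ``pathway_fidelity`` f, each member of module k is labelled with the
    module's own pathway with probability f and with a random decoy pathway
    otherwise; all remaining features are partitioned into decoy pathways of
    roughly ``decoy_pathway_size``. Pathway sizes therefore sum to the
    universe size.
    """
    rng = config._streams()["annotation"]
    feats = _feature_ids(config)
    in_module = {f: k for k, mem in enumerate(truth.module_members) for f in mem}
    n_decoys = max(
        1, (len(feats) - len(in_module)) // config.decoy_pathway_size
    )
    decoys = [f"decoy_pathway_{j + 1:03d}" for j in range(n_decoys)]
    module_pathways = [
        f"module_pathway_{k + 1:02d}" for k in range(len(truth.module_members))
    ]
    sub = {}
    free = []
    for f in feats:
        k = in_module.get(f)
        if k is not None and rng.random() < config.pathway_fidelity:
            sub[f] = module_pathways[k]
        else:
            free.append(f)
    rng.shuffle(free)
    for j, f in enumerate(free):
        sub[f] = decoys[j % n_decoys]

    supers = [f"super_{i + 1}" for i in range(8)]
    all_paths = sorted(set(sub.values()))
    super_of = {pth: supers[i % len(supers)] for i, pth in enumerate(all_paths)}

    annotation = pd.DataFrame(
        {
            "panel": ["HD4" if f.startswith("HD4") else "CLP" for f in feats],
            "super_pathway": [super_of[sub[f]] for f in feats],
            "sub_pathway": [sub[f] for f in feats],
        },
        index=pd.Index(feats, name="feature_id"),
    )
    truth.module_pathways = module_pathways
    return annotation, annotation["sub_pathway"]


def simulate_proteome(
    config: SimulationConfig,
    truth: GroundTruth,
    cohort: pd.DataFrame,
    sample_ids: list[str] | None = None,
) -> tuple[Dataset, GroundTruth]:
    """Protein panel whose first latents track chosen metabolite latents.

    Protein latent w_k = rho * z_k + sqrt(1 - rho^2) * eps for the shared
    modules (rho = ``latent_correlation``); remaining protein modules are
    independent. By default the matrix is restricted to a proteome subset of
    ``n_proteome_case`` cases and ``n_proteome_control`` controls, mirroring
    partial assay overlap.
    """
    if config.n_shared_latents > config.n_protein_modules:
        raise ValueError("n_shared_latents cannot exceed n_protein_modules")
    if config.n_shared_latents > len(truth.module_members):
        raise ValueError("n_shared_latents cannot exceed the metabolite module count")
    rng = config._streams()["proteome"]

    if sample_ids is None:
        cases = cohort.index[cohort["group"] == "case"][: config.n_proteome_case]
        ctrls = cohort.index[cohort["group"] == "control"][: config.n_proteome_control]
        if len(cases) < config.n_proteome_case or len(ctrls) < config.n_proteome_control:
            raise ValueError("cohort too small for the requested proteome subset")
        sample_ids = list(cases) + list(ctrls)
    sub_cohort = cohort.loc[sample_ids]
    n = len(sample_ids)

    prots = [f"P_{i + 1:04d}" for i in range(config.n_proteins)]
    q = config.n_protein_modules
    rho = config.latent_correlation
    w = _draw_latents(rng, n, q, config.latent_dist)
    shared: dict[int, int] = {}
    z = truth.latent_scores.loc[sample_ids]
    for k in range(config.n_shared_latents):
        zk = z.iloc[:, k].to_numpy()
        zk = (zk - zk.mean()) / zk.std()
        w[:, k] = rho * zk + np.sqrt(max(0.0, 1 - rho**2)) * w[:, k]
        shared[k] = k

    lo, hi = config.protein_module_size_range
    if q * hi > config.n_proteins:
        raise ValueError("protein module sizes exceed the number of proteins")
    perm = rng.permutation(config.n_proteins)
    sizes = rng.integers(lo, hi + 1, size=q)
    members: list[list[str]] = []
    start = 0
    for s in sizes:
        members.append(sorted(prots[j] for j in perm[start : start + s]))
        start += s

    loadings = np.zeros((config.n_proteins, q))
    pidx = {f: j for j, f in enumerate(prots)}
    for k, mem in enumerate(members):
        mag = rng.uniform(0.5, 1.0, size=len(mem))
        sign = rng.choice([-1.0, 1.0], size=len(mem))
        for f, l in zip(mem, mag * sign):
            loadings[pidx[f], k] = l

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_proteins)
    noise = rng.normal(0.0, config.noise_sd, size=(n, config.n_proteins))
    values = baseline + w @ loadings.T + noise

    matrix = pd.DataFrame(values, index=sub_cohort.index, columns=prots)
    annotation = pd.DataFrame(
        {
            "panel": "OLINK",
            "super_pathway": "protein",
            "sub_pathway": [f"protein_group_{j % 12 + 1:02d}" for j in range(config.n_proteins)],
        },
        index=pd.Index(prots, name="feature_id"),
    )
    prot_truth = GroundTruth(
        module_members=members,
        latent_scores=pd.DataFrame(
            w, index=sub_cohort.index, columns=[f"W{k + 1}" for k in range(q)]
        ),
        affected_modules=[],
        differential_features={},
        batch_params=pd.DataFrame(
            {"shift": np.zeros(config.n_proteins), "scale": np.ones(config.n_proteins)},
            index=prots,
        ),
        shared_latents=shared,
    )
    dataset = Dataset(abundance=matrix, samples=sub_cohort, annotation=annotation)
    return dataset, prot_truth


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Cohort + metabolome + annotation bundled into an aligned Dataset."""
    cohort = simulate_cohort(config)
    matrix, truth = simulate_metabolome(config, cohort)
    annotation, _ = simulate_annotation(config, truth)
    return Dataset(abundance=matrix, samples=cohort, annotation=annotation), truth
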