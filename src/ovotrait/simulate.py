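"""Synthetic comparative dataset generator.

Emulates the study design the package analyses: ~71 passerine species on an
ultrametric phylogeny, three museum eggs per species, two positively
correlated eggshell pigments (protoporphyrin, biliverdin; log10 ug per g
shell) evolving with strong phylogenetic signal, life-history/nesting
covariates carrying their own signal, and egg photographs whose background
CIELAB color and maculation are driven by the pigment values.

The generating model is triangular: covariates are Brownian-motion traits
(binary ones by thresholding a BM liability at its median, so both levels
are always present and the trait is phylogenetically plausible); log10
biliverdin is a linear function of the covariates plus BM-structured error;
log10 protoporphyrin adds a cross-pigment term on biliverdin.  Replicate
(within-species) noise is i.i.d. Gaussian on the log10 scale with SD set
from a target repeatability (ICC).  Per-area concentrations are derived
from per-mass values through shell thickness and material density with
multiplicative noise.

Everything is deterministic given the config seed; the tree, trait and
image random streams are split from the master seed so changing image
settings never perturbs the trait draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import warnings

import numpy as np
import pandas as pd

from .phylosignal import apply_lambda
from .render import EggImageBundle, render_egg_image
from .trees import simulate_yule_tree, tree_covariance

__all__ = [
    "SimulationConfig",
    "simulate_bm_traits",
    "simulate_species_dataset",
    "SimulatedDataset",
    "DEFAULT_EFFECTS_PROTOPORPHYRIN",
    "DEFAULT_EFFECTS_BILIVERDIN",
]

# Default generating coefficients for the two pigment responses on the
# log10 ug/g scale.  Binary covariates are 0/1 indicators (open nest,
# off-ground nest, parasitized); thickness enters in mm, body mass as log10 g.
DEFAULT_EFFECTS_PROTOPORPHYRIN: dict[str, float] = {
    "intercept": 1.65,
    "log10_biliverdin": 0.36,
    "nest_location": 0.002,
    "parasitized": 0.11,
    "nest_type": 0.19,
    "log10_body_mass": -0.28,
    "clutch_size": -0.09,
    "shell_thickness_mm": 2.29,
}
DEFAULT_EFFECTS_BILIVERDIN: dict[str, float] = {
    "intercept": -0.71,
    "nest_location": -0.15,
    "parasitized": -0.11,
    "nest_type": 0.03,
    "log10_body_mass": 0.28,
    "clutch_size": 0.06,
    "shell_thickness_mm": 6.47,
}


@dataclass
class SimulationConfig:
    """Full provenance of a synthetic dataset."""

    seed: int = 0
    n_species: int = 71
    n_replicates: int = 3
    birth_rate: float = 1.0
    lambda_true: float = 1.0
    sigma2: float = 0.05  #: pigment BM rate (log10 units^2 per unit branch length)
    pigment_correlation: float = 0.6
    icc_protoporphyrin: float = 0.76
    icc_biliverdin: float = 0.62
    effects_protoporphyrin: dict = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS_PROTOPORPHYRIN)
    )
    effects_biliverdin: dict = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS_BILIVERDIN)
    )
    # image rendering
    canvas_height: int = 300
    canvas_width: int = 400
    pixel_scale: float = 0.1  #: mm per pixel
    noise_sd: float = 0.004
    base_maculation: float = 0.12
    maculation_slope: float = 0.10
    vignette_strength: float = 0.0
    # per-area derivation
    shell_density_g_mm3: float = 0.002
    area_noise_sd: float = 0.06  #: SD of log10 multiplicative noise

    def validate(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if not -1.0 < self.pigment_correlation < 1.0:
            raise ValueError("pigment_correlation must be in (-1, 1)")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if not 0.0 <= self.base_maculation <= 1.0:
            raise ValueError("base_maculation must be in [0, 1]")
        for icc in (self.icc_protoporphyrin, self.icc_biliverdin):
            if not 0.0 < icc <= 1.0:
                raise ValueError("target ICCs must be in (0, 1]")

    def as_dict(self) -> dict:
        return asdict(self)


def simulate_bm_traits(
    tree=None,
    sigma2: float = 1.0,
    lam: float = 1.0,
    n_traits: int = 1,
    correlation: float = 0.0,
    mu: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    V: np.ndarray | None = None,
    labels=None,
) -> tuple[np.ndarray, list[str]]:
    """Draw tip values under (lambda-rescaled) Brownian motion.

    Tips are multivariate normal with covariance ``sigma2 * V(lambda)``;
    with several traits, the traits' independent components share an
    exchangeable cross-trait correlation.

    Returns ``(values, labels)`` with ``values`` of shape
    ``(n_tips, n_traits)``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if not -1.0 < correlation < 1.0:
        raise ValueError("correlation must lie in (-1, 1)")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if V is None:
        V, labels = tree_covariance(tree)
    labels = list(labels) if labels is not None else [f"t{i}" for i in range(V.shape[0])]
    if rng is None:
        rng = np.random.default_rng(seed)
    n = V.shape[0]
    Z = rng.standard_normal((n, n_traits))
    if n_traits > 1 and correlation != 0.0:
        C = np.full((n_traits, n_traits), correlation)
        np.fill_diagonal(C, 1.0)
        Z = Z @ np.linalg.cholesky(C).T
    if sigma2 == 0.0:
        return np.full((n, n_traits), mu), labels
    Vl = apply_lambda(V, lam)
    # tiny jitter guards exact-duplicate rows on degenerate trees
    L = np.linalg.cholesky(sigma2 * Vl + 1e-12 * np.eye(n))
    return mu + L @ Z, labels


@dataclass
class SimulatedDataset:
    """A complete synthetic study: tree, replicate-level traits, image specs."""

    config: SimulationConfig
    tree: object
    traits: pd.DataFrame  #: one row per species x replicate
    species_table: pd.DataFrame  #: species-level generating values
    image_params: pd.DataFrame  #: per-image rendering parameters + seed

    def species_means(self) -> pd.DataFrame:
        """Species-mean table used by the comparative analyses."""
        num = (
            self.traits.drop(columns=["replicate"])
            .groupby("species")
            .mean(numeric_only=True)
        )
        firsts = self.traits.groupby("species")[
            ["nest_type", "nest_location", "parasitized"]
        ].first()
        return num.join(firsts)

    def render_image(self, image_id: str) -> EggImageBundle:
        """Render one egg image bundle from its stored parameters."""
        row = self.image_params.loc[image_id]
        return render_egg_image(
            background_lab=(row["bg_L"], row["bg_a"], row["bg_b"]),
            maculation_fraction=row["maculation_fraction"],
            pixel_scale=self.config.pixel_scale,
            seed=int(row["image_seed"]),
            shape=(self.config.canvas_height, self.config.canvas_width),
            noise_sd=self.config.noise_sd,
            vignette_strength=self.config.vignette_strength,
        )

    def iter_images(self):
        for image_id in self.image_params.index:
            yield image_id, self.render_image(image_id)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _binary_from_liability(z: np.ndarray) -> np.ndarray:
    """Threshold a liability at its median -> balanced 0/1 indicator."""
    ind = (z > np.median(z)).astype(int)
    if ind.sum() in (0, len(ind)):  # ties at the median could collapse a level
        warnings.warn("degenerate binary covariate; forcing both levels", stacklevel=2)
        ind[np.argsort(z)[: len(ind) // 2]] = 0
        ind[np.argsort(z)[len(ind) // 2 :]] = 1
    return ind


def simulate_species_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic study defined by ``config``."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    ss_tree, ss_traits, ss_images = ss.spawn(3)
    rng_tree = np.random.default_rng(ss_tree)
    rng_traits = np.random.default_rng(ss_traits)
    rng_images = np.random.default_rng(ss_images)

    tree = simulate_yule_tree(
        config.n_species, birth_rate=config.birth_rate, rng=rng_tree
    )
    V, species = tree_covariance(tree)
    n = len(species)

    # covariate liabilities: independent unit-rate BM traits
    liab, _ = simulate_bm_traits(
        V=V, labels=species, sigma2=1.0, lam=1.0, n_traits=6, rng=rng_traits
    )
    z = {name: _standardize(liab[:, i]) for i, name in enumerate(
        ["nest_type", "nest_location", "parasitized", "thickness", "clutch", "mass"]
    )}
    nest_type = _binary_from_liability(z["nest_type"])        # 1 = open
    nest_location = _binary_from_liability(z["nest_location"])  # 1 = off ground
    parasitized = _binary_from_liability(z["parasitized"])    # 1 = yes
    thickness_mm = np.clip(0.09 + 0.02 * z["thickness"], 0.04, 0.20)
    clutch_size = np.clip(4.5 + 1.2 * z["clutch"], 1.5, None)
    log10_body_mass = 1.2 + 0.35 * z["mass"]

    # BM-structured pigment errors, cross-correlated
    err, _ = simulate_bm_traits(
        V=V, labels=species, sigma2=config.sigma2, lam=config.lambda_true,
        n_traits=2, correlation=config.pigment_correlation, rng=rng_traits,
    )
    covs = {
        "nest_type": nest_type,
        "nest_location": nest_location,
        "parasitized": parasitized,
        "shell_thickness_mm": thickness_mm,
        "clutch_size": clutch_size,
        "log10_body_mass": log10_body_mass,
    }

    def linpred(effects: dict, extra: dict | None = None) -> np.ndarray:
        out = np.full(n, effects.get("intercept", 0.0))
        table = dict(covs)
        if extra:
            table.update(extra)
        for name, beta in effects.items():
            if name == "intercept":
                continue
            if name not in table:
                raise KeyError(f"unknown effect term {name!r}")
            out = out + beta * table[name]
        return out

    log10_biliv = linpred(config.effects_biliverdin) + err[:, 0]
    log10_proto = linpred(
        config.effects_protoporphyrin, extra={"log10_biliverdin": log10_biliv}
    ) + err[:, 1]

    # replicate noise SD from the target ICC and realised between-species var
    def within_sd(species_vals: np.ndarray, icc: float) -> float:
        vb = species_vals.var(ddof=1)
        return float(np.sqrt(vb * (1.0 - icc) / icc)) if icc < 1.0 else 0.0

    sd_p = within_sd(log10_proto, config.icc_protoporphyrin)
    sd_b = within_sd(log10_biliv, config.icc_biliverdin)

    k = config.n_replicates
    rows = []
    for i, sp in enumerate(species):
        for rep in range(1, k + 1):
            lp = log10_proto[i] + rng_traits.normal(0.0, sd_p)
            lb = log10_biliv[i] + rng_traits.normal(0.0, sd_b)
            conc_p = 10.0**lp
            conc_b = 10.0**lb
            mass_per_area = thickness_mm[i] * config.shell_density_g_mm3  # g/mm^2
            noise_a = 10.0 ** rng_traits.normal(0.0, config.area_noise_sd, size=2)
            rows.append(
                {
                    "species": sp,
                    "replicate": rep,
                    "log10_protoporphyrin": lp,
                    "log10_biliverdin": lb,
                    "protoporphyrin_ug_g": conc_p,
                    "biliverdin_ug_g": conc_b,
                    "protoporphyrin_ug_mm2": conc_p * mass_per_area * noise_a[0],
                    "biliverdin_ug_mm2": conc_b * mass_per_area * noise_a[1],
                    "shell_thickness_um": thickness_mm[i] * 1000.0,
                    "clutch_size": clutch_size[i],
                    "body_mass_g": 10.0 ** log10_body_mass[i],
                    "nest_type": "open" if nest_type[i] else "cavity",
                    "nest_location": "off_ground" if nest_location[i] else "ground",
                    "parasitized": "yes" if parasitized[i] else "no",
                }
            )
    traits = pd.DataFrame(rows)

    species_table = pd.DataFrame(
        {
            "species": species,
            "log10_protoporphyrin_true": log10_proto,
            "log10_biliverdin_true": log10_biliv,
            "shell_thickness_mm": thickness_mm,
            "clutch_size": clutch_size,
            "log10_body_mass": log10_body_mass,
            "nest_type": nest_type,
            "nest_location": nest_location,
            "parasitized": parasitized,
        }
    ).set_index("species")

    # image parameters: background CIELAB and spot coverage driven by the
    # replicate pigment values with the study's observed sign structure
    # (L* falls with both pigments, a* rises with protoporphyrin and falls
    # with biliverdin, maculation rises with protoporphyrin)
    zp = _standardize(traits["log10_protoporphyrin"].to_numpy())
    zb = _standardize(traits["log10_biliverdin"].to_numpy())
    bg_L = np.clip(70.0 - 12.0 * zp - 10.0 * zb, 20.0, 92.0)
    bg_a = np.clip(12.0 + 6.0 * zp - 9.0 * zb, -25.0, 35.0)
    bg_b = np.clip(25.0 + 3.0 * zp - 4.0 * zb, 0.0, 45.0)
    frac = np.clip(
        config.base_maculation + config.maculation_slope * zp, 0.0, 0.45
    )
    image_seeds = rng_images.integers(0, 2**31 - 1, size=len(traits))
    image_params = pd.DataFrame(
        {
            "image_id": [
                f"{r.species}_egg{r.replicate}" for r in traits.itertuples()
            ],
            "species": traits["species"].to_numpy(),
            "replicate": traits["replicate"].to_numpy(),
            "bg_L": bg_L,
            "bg_a": bg_a,
            "bg_b": bg_b,
            "maculation_fraction": frac,
            "image_seed": image_seeds,
        }
    ).set_index("image_id")

    return SimulatedDataset(
        config=config,
        tree=tree,
        traits=traits,
        species_table=species_table,
        image_params=image_params,
    )
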