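"""Synthetic multi-site cohort generator with known asymmetry ground truth.

Produces phenotype tables (multi-site, male-skewed, three symptom-dominance
subpopulations) and blob-phantom GM probability volumes on a symmetric grid
with configurable localized asymmetry effects, so the full analysis chain
can be exercised against a known manifest without downloading anything.

Subject volumes are template blobs with one hemisphere's effect region
scaled by ``(1 + delta)``, plus a smooth per-site bias field, an optional
age trend, and smooth subject noise. The latent regional asymmetry index
implied by a multiplicative effect ``delta`` is ``2*delta / (2 + delta)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .asymmetry import fwhm_to_sigma
from .volume import GMVolume, centered_affine

__all__ = [
    "CohortConfig",
    "EffectSpec",
    "GroundTruthManifest",
    "SimulatedCohort",
    "default_template_blobs",
    "effect_region_mask",
    "generate_phenotypes",
    "generate_subject_volume",
    "generate_template",
    "latent_ai",
    "simulate_cohort",
    "smooth_noise_field",
]

#: Subgroup proportions of the emulated cohort (SI : VA : RRB = 146 : 43 : 41).
DEFAULT_PROPORTIONS = (146 / 230, 43 / 230, 41 / 230)

#: Unequal relative site sizes (largest-first), cycled if more sites are asked.
_SITE_WEIGHT_PATTERN = (65, 56, 52, 25, 24, 20, 14, 9)

_SUBGROUPS = ("SI", "VA", "RRB")


@dataclass
class CohortConfig:
    n_asd: int = 60
    n_td: int = 60
    n_sites: int = 8
    age_range: tuple[float, float] = (7.0, 18.0)
    male_fraction: float = 0.85
    subgroup_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size: float = 3.0
    seed: int = 0
    max_scores: tuple[float, float, float] = (30.0, 26.0, 12.0)
    ados_fraction: float = 0.6
    noise_sd: float = 0.03
    noise_fwhm_mm: float = 6.0
    site_bias_sd: float = 0.01
    age_volume_coef: float = 0.003  # symmetric whole-volume scaling per year

    def __post_init__(self) -> None:
        props = np.asarray(self.subgroup_proportions, dtype=np.float64)
        if props.min() < 0 or props.max() > 1:
            raise ValueError("subgroup proportions must lie in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("subgroup proportions must sum to 1")
        if self.grid_shape[0] % 2 != 0:
            raise ValueError("grid extent across the midline must be even")
        if self.n_asd < 0 or self.n_td < 0 or self.n_sites < 1:
            raise ValueError("invalid cohort sizes")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing")

    @property
    def affine(self) -> np.ndarray:
        return centered_affine(self.grid_shape, self.voxel_size)

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


@dataclass
class EffectSpec:
    """One localized multiplicative asymmetry effect.

    ``delta`` scales the template inside a ball of ``region_radius`` mm
    around ``region_center`` on the chosen hemisphere by ``(1 + delta)``.
    ``target`` selects who carries it: the whole ASD group or one subgroup.
    ``subject_sd`` adds per-subject Gaussian variation to delta (needed for
    a nonzero behavior coupling). ``behavior_coupling`` requests a target
    partial correlation between the latent regional AI and a named score.
    """

    region_center: tuple[float, float, float]
    region_radius: float
    delta: float
    side: str = "right"  # "right" | "left"
    target: str = "general_ASD"  # general_ASD | SI | VA | RRB
    age_slope: float | None = None  # AI units per year
    behavior_coupling: tuple[str, float] | None = None  # (score column, rho)
    subject_sd: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if abs(self.delta) >= 1:
            raise ValueError("|delta| must be < 1")
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")
        if self.target not in ("general_ASD",) + _SUBGROUPS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.behavior_coupling is not None:
            score, rho = self.behavior_coupling
            if not -1 < rho < 1:
                raise ValueError("behavior coupling rho must be in (-1, 1)")
            if self.subject_sd <= 0:
                raise ValueError("behavior coupling needs subject_sd > 0")
        if not self.name:
            self.name = f"{self.target}_{self.side}"

    def validate_against(self, config: CohortConfig) -> None:
        if self.region_radius <= config.voxel_size:
            raise ValueError("region radius must exceed the voxel size")
        half = np.asarray(config.grid_shape) * config.voxel_size / 2.0
        center = np.abs(np.asarray(self.region_center))
        if (center + self.region_radius > half).any():
            raise ValueError(f"effect region {self.name} extends outside the grid")

    def applies_to(self, diagnosis: str, subgroup: str | None) -> bool:
        if diagnosis != "ASD":
            return False
        if self.target == "general_ASD":
            return True
        return subgroup == self.target


def latent_ai(delta: float) -> float:
    """Regional AI implied by scaling one hemisphere by (1 + delta)."""
    return 2.0 * delta / (2.0 + delta)


@dataclass
class GroundTruthManifest:
    """Everything the generator injected, keyed for later recovery checks."""

    seed: int
    effects: list[EffectSpec]
    latents: dict[str, dict[str, float]]  # subject_id -> effect name -> latent AI
    deltas: dict[str, dict[str, float]]  # subject_id -> effect name -> delta

    def to_json(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "effects": [asdict(e) for e in self.effects],
            "latents": self.latents,
            "deltas": self.deltas,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        effects = []
        for d in payload["effects"]:
            d = dict(d)
            d["region_center"] = tuple(d["region_center"])
            if d.get("behavior_coupling"):
                d["behavior_coupling"] = tuple(d["behavior_coupling"])
            effects.append(EffectSpec(**d))
        return cls(payload["seed"], effects, payload["latents"], payload["deltas"])


# ---------------------------------------------------------------------------
# phenotypes


def _site_weights(n_sites: int) -> np.ndarray:
    reps = int(np.ceil(n_sites / len(_SITE_WEIGHT_PATTERN)))
    w = np.tile(np.asarray(_SITE_WEIGHT_PATTERN, dtype=np.float64), reps)[:n_sites]
    # decay repeated cycles so sizes stay distinct-ish
    decay = np.repeat(0.7 ** np.arange(reps), len(_SITE_WEIGHT_PATTERN))[:n_sites]
    w = w * decay
    return w / w.sum()


def _sample_adir_scores(
    rng: np.random.Generator,
    dominant: int,
    max_scores: Sequence[float],
    max_retries: int = 1000,
) -> tuple[int, int, int]:
    """Integer subscale scores whose normalized values make ``dominant``
    the strict maximum with no pairwise ties (rejection sampling)."""
    maxima = np.asarray(max_scores, dtype=np.float64)
    for _ in range(max_retries):
        target = np.empty(3)
        target[dominant] = rng.uniform(0.55, 0.95)
        lo = 0.05
        for j in range(3):
            if j != dominant:
                target[j] = rng.uniform(lo, target[dominant] - 0.08)
        scores = np.rint(target * maxima).astype(int)
        norm = scores / maxima
        others = [norm[j] for j in range(3) if j != dominant]
        if norm[dominant] <= max(others):
            continue
        if len({norm[0], norm[1], norm[2]}) == 3:
            return int(scores[0]), int(scores[1]), int(scores[2])
    raise RuntimeError("could not sample tie-free ADI-R scores; check max_scores")


def generate_phenotypes(config: CohortConfig) -> pd.DataFrame:
    """Multi-site phenotype table with injected subgroup dominance labels.

    ASD rows carry ADI-R subscale integers whose normalized values make the
    intended label the strict maximum; TD rows carry none. A configurable
    fraction of ASD rows carries a (baseline, uncoupled) ADOS social score.
    Column conventions: DX_GROUP 1 = ASD, 2 = TD; SEX 1 = male, 2 = female.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_asd + config.n_td
    weights = _site_weights(config.n_sites)
    sites = rng.choice(config.n_sites, size=n, p=weights)
    ages = rng.uniform(*config.age_range, size=n)
    sex = np.where(rng.random(n) < config.male_fraction, 1, 2)
    dx = np.concatenate([np.ones(config.n_asd, int), np.full(config.n_td, 2)])
    labels = rng.choice(3, size=config.n_asd, p=config.subgroup_proportions)

    rows = []
    for i in range(n):
        sub_id = f"S{i + 1:05d}"
        row = {
            "SUB_ID": sub_id,
            "SITE_ID": f"SITE{sites[i] + 1:02d}",
            "DX_GROUP": int(dx[i]),
            "AGE_AT_SCAN": float(np.round(ages[i], 2)),
            "SEX": int(sex[i]),
            "ADI_R_SOCIAL_TOTAL_A": np.nan,
            "ADI_R_VERBAL_TOTAL_BV": np.nan,
            "ADI_RRB_TOTAL_C": np.nan,
            "ADOS_SOCIAL": np.nan,
            "TRUE_SUBGROUP": "",
        }
        if dx[i] == 1:
            dom = int(labels[i])
            s, v, r = _sample_adir_scores(rng, dom, config.max_scores)
            row["ADI_R_SOCIAL_TOTAL_A"] = s
            row["ADI_R_VERBAL_TOTAL_BV"] = v
            row["ADI_RRB_TOTAL_C"] = r
            row["TRUE_SUBGROUP"] = _SUBGROUPS[dom]
            if rng.random() < config.ados_fraction:
                row["ADOS_SOCIAL"] = int(rng.integers(4, 15))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# volumes


def default_template_blobs(config: CohortConfig) -> list[dict]:
    """One large right-hemisphere ellipsoidal blob, scaled to the grid.

    Mirrored during template generation, it yields a brain-like pair of
    hemispheric GM masses.
    """
    half = np.asarray(config.grid_shape) * config.voxel_size / 2.0
    return [
        {
            "center": (0.40 * half[0], 0.0, 0.0),
            "sigma": (0.30 * half[0], 0.35 * half[1], 0.30 * half[2]),
            "amplitude": 0.85,
        }
    ]


def _world_grids(config: CohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    aff = config.affine
    coords = []
    for j, nj in enumerate(config.grid_shape):
        coords.append(aff[j, j] * np.arange(nj) + aff[j, 3])
    return coords[0], coords[1], coords[2]


def generate_template(config: CohortConfig, blob_spec: list[dict] | None) -> GMVolume:
    """Sum of Gaussian blobs mirrored exactly across the mid-sagittal plane.

    Blob centers are given for one hemisphere (or on the midline); each
    off-midline blob is added together with its mirror image, so the result
    equals its own left-right flip bit-exactly. Values are clipped to [0, 1].
    """
    xs, ys, zs = _world_grids(config)
    data = np.zeros(config.grid_shape, dtype=np.float64)
    for blob in blob_spec or []:
        cx, cy, cz = blob["center"]
        sig = np.broadcast_to(np.asarray(blob["sigma"], dtype=float), (3,))
        amp = float(blob["amplitude"])
        half = np.asarray(config.grid_shape) * config.voxel_size / 2.0
        if (np.abs([cx, cy, cz]) > half).any():
            raise ValueError("blob center outside the grid")
        centers_x = (cx,) if cx == 0 else (cx, -cx)
        for cxi in centers_x:
            gx = np.exp(-((xs - cxi) ** 2) / (2 * sig[0] ** 2))
            gy = np.exp(-((ys - cy) ** 2) / (2 * sig[1] ** 2))
            gz = np.exp(-((zs - cz) ** 2) / (2 * sig[2] ** 2))
            data += amp * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    np.clip(data, 0.0, 1.0, out=data)
    return GMVolume(data, config.affine)


def effect_region_mask(config: CohortConfig, effect: EffectSpec) -> np.ndarray:
    """Boolean ball on the effect's hemisphere (mirrors center for 'left')."""
    cx, cy, cz = effect.region_center
    if effect.side == "left":
        cx = -abs(cx)
    else:
        cx = abs(cx)
    xs, ys, zs = _world_grids(config)
    d2 = (
        (xs[:, None, None] - cx) ** 2
        + (ys[None, :, None] - cy) ** 2
        + (zs[None, None, :] - cz) ** 2
    )
    return d2 <= effect.region_radius**2


def smooth_noise_field(
    shape: tuple[int, int, int],
    voxel_size: float,
    fwhm_mm: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian random field: smoothed white noise rescaled to the target sd."""
    white = rng.standard_normal(shape)
    if fwhm_mm <= 0:
        return sd * white
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_size
    smoothed = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    s = smoothed.std()
    if s == 0:
        return np.zeros(shape)
    return sd / s * smoothed


def _site_index(site_id: str) -> int:
    return int("".join(ch for ch in site_id if ch.isdigit()) or 0)


def generate_subject_volume(
    template: GMVolume,
    record: pd.Series,
    effects: Sequence[EffectSpec],
    seed: int,
    config: CohortConfig,
    deltas: dict[str, float] | None = None,
) -> GMVolume:
    """Realize one subject's GM volume from the template.

    Applies each effect carried by the subject (template scaled by
    ``1 + delta`` inside the region ball on the chosen side), a smooth
    per-site bias field (same field for every subject of a site), a
    symmetric whole-volume age scaling, and smooth subject noise; values
    are clipped to [0, 1]. ``deltas`` (by effect name) override the nominal
    per-effect deltas — the cohort driver passes the manifest values here.
    """
    data = template.data.copy()
    subgroup = record.get("TRUE_SUBGROUP") or None
    diagnosis = "ASD" if int(record["DX_GROUP"]) == 1 else "TD"
    for eff in effects:
        if not eff.applies_to(diagnosis, subgroup):
            continue
        d = eff.delta if deltas is None else deltas.get(eff.name, eff.delta)
        if d == 0:
            continue
        ball = effect_region_mask(config, eff)
        data[ball] *= 1.0 + d

    # symmetric whole-volume age scaling (no asymmetry contribution)
    if config.age_volume_coef:
        data *= 1.0 + config.age_volume_coef * (
            float(record["AGE_AT_SCAN"]) - config.age_mid
        )

    if config.site_bias_sd > 0:
        site_rng = np.random.default_rng(
            (config.seed, 7919, _site_index(str(record["SITE_ID"])))
        )
        data += smooth_noise_field(
            template.shape,
            config.voxel_size,
            config.noise_fwhm_mm,
            config.site_bias_sd,
            site_rng,
        )

    if config.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += smooth_noise_field(
            template.shape,
            config.voxel_size,
            config.noise_fwhm_mm,
            config.noise_sd,
            rng,
        )
    np.clip(data, 0.0, 1.0, out=data)
    return template.like(data)


# ---------------------------------------------------------------------------
# cohort driver


@dataclass
class SimulatedCohort:
    """Phenotypes + template + manifest, with lazy per-subject volumes."""

    config: CohortConfig
    phenotypes: pd.DataFrame
    template: GMVolume
    manifest: GroundTruthManifest
    effects: list[EffectSpec] = field(default_factory=list)

    def subject_volume(self, sub_id: str) -> GMVolume:
        idx = int(self.phenotypes.index[self.phenotypes["SUB_ID"] == sub_id][0])
        record = self.phenotypes.loc[idx]
        return generate_subject_volume(
            self.template,
            record,
            self.effects,
            seed=_volume_seed(self.config.seed, idx),
            config=self.config,
            deltas=self.manifest.deltas.get(sub_id),
        )

    def iter_volumes(self, sub_ids: Sequence[str] | None = None):
        ids = list(sub_ids) if sub_ids is not None else list(self.phenotypes["SUB_ID"])
        for sid in ids:
            yield sid, self.subject_volume(sid)


def _volume_seed(base_seed: int, idx: int) -> tuple[int, int, int]:
    return (base_seed, 104729, idx)


def _draw_manifest(
    config: CohortConfig,
    pheno: pd.DataFrame,
    effects: Sequence[EffectSpec],
) -> GroundTruthManifest:
    latents: dict[str, dict[str, float]] = {}
    deltas: dict[str, dict[str, float]] = {}
    for idx, record in pheno.iterrows():
        diagnosis = "ASD" if int(record["DX_GROUP"]) == 1 else "TD"
        subgroup = record.get("TRUE_SUBGROUP") or None
        eff_rng = np.random.default_rng((config.seed, 15485863, int(idx)))
        sub_l: dict[str, float] = {}
        sub_d: dict[str, float] = {}
        for eff in effects:
            if not eff.applies_to(diagnosis, subgroup):
                continue
            d = eff.delta
            if eff.age_slope:
                # convert the requested AI/year trend into a delta offset
                ai_shift = eff.age_slope * (
                    float(record["AGE_AT_SCAN"]) - config.age_mid
                )
                d = d + 2.0 * ai_shift / max(1e-9, 2.0 - ai_shift)
            if eff.subject_sd > 0:
                d = d + eff.subject_sd * eff_rng.standard_normal()
            d = float(np.clip(d, -0.95, 0.95))
            sub_d[eff.name] = d
            sub_l[eff.name] = latent_ai(d)
        latents[str(record["SUB_ID"])] = sub_l
        deltas[str(record["SUB_ID"])] = sub_d
    return GroundTruthManifest(config.seed, list(effects), latents, deltas)


def _couple_ados(
    config: CohortConfig,
    pheno: pd.DataFrame,
    manifest: GroundTruthManifest,
    ados_loc: float = 9.0,
    ados_sd: float = 2.5,
) -> None:
    """Overwrite coupled score columns so that, in expectation, the partial
    correlation between the latent regional AI and the score equals rho.

    With score = a + b*latent + e and e ~ N(0, sd_e), the correlation is
    ``b*sd_latent / sqrt(b^2 sd_latent^2 + sd_e^2)``, so
    ``b = rho * sd_e / (sd_latent * sqrt(1 - rho^2))``.
    """
    rng = np.random.default_rng((config.seed, 32452843))
    for eff in manifest.effects:
        if eff.behavior_coupling is None:
            continue
        score_col, rho = eff.behavior_coupling
        carriers = [
            sid
            for sid in pheno["SUB_ID"]
            if eff.name in manifest.latents[str(sid)]
        ]
        lat = np.array([manifest.latents[str(s)][eff.name] for s in carriers])
        sd_lat = lat.std(ddof=1)
        if sd_lat == 0:
            raise ValueError(f"no latent variance for coupled effect {eff.name}")
        b = rho * ados_sd / (sd_lat * np.sqrt(1.0 - rho**2))
        scores = ados_loc + b * (lat - lat.mean()) + ados_sd * rng.standard_normal(
            len(carriers)
        )
        scores = np.clip(np.rint(scores), 0, None)
        if score_col not in pheno.columns:
            pheno[score_col] = np.nan
        pheno[score_col] = pheno[score_col].astype(np.float64)
        sel = pheno["SUB_ID"].isin(carriers)
        has_ados = sel & pheno["ADOS_SOCIAL"].notna()
        order = {s: float(v) for s, v in zip(carriers, scores)}
        pheno.loc[has_ados, score_col] = [
            order[s] for s in pheno.loc[has_ados, "SUB_ID"]
        ]


def simulate_cohort(
    config: CohortConfig,
    effects: Sequence[EffectSpec] = (),
    blob_spec: list[dict] | None = None,
    couple_scores: bool = True,
) -> SimulatedCohort:
    """Generate phenotypes, template, and the ground-truth manifest.

    Volumes are produced lazily by :meth:`SimulatedCohort.subject_volume`
    so large cohorts never need to be memory-resident at once. Regenerating
    with the same config reproduces phenotypes and manifest bit-exactly.
    """
    effects = list(effects)
    for eff in effects:
        eff.validate_against(config)
    if blob_spec is None:
        blob_spec = default_template_blobs(config)
    pheno = generate_phenotypes(config)
    template = generate_template(config, blob_spec)
    manifest = _draw_manifest(config, pheno, effects)
    if couple_scores:
        _couple_ados(config, pheno, manifest)
    return SimulatedCohort(config, pheno, template, manifest, effects)
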