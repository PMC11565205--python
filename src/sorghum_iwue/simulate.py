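"""Synthetic glasshouse-trial generator with known ground truth.

Emulates an 89-genotype x 2-treatment (well-watered / water-stressed) sorghum
screen with 3 pot replicates per cell, so that every downstream stage —
hydraulics, iWUE partitioning, change vectors, variance components, haplotype
contrasts — can be tested against known effect vectors.

Generative model (fixed; all randomness flows from one seed):

* log g_s = log(gs_base * ws_gs_factor^[WS]) + G_i + GT_it + eps_ijt, with
  genotype, genotype-x-treatment and replicate effects drawn as independent
  zero-mean normals (lognormal g_s guarantees positivity and the right-skewed
  spread seen in real screens).
* A photosynthetic-capacity multiplier c_i = exp(pc_i), pc_i ~ N(0,
  pc_sigma_g^2), optionally scaled under WS by a per-genotype
  ws_capacity_factor (capacity maintenance vs loss under stress).
* A_n = c_i * A_max * g_s / (g_s + K_half): a saturating A_n–g_s curve.
* C_i = C_a - 1.6 A_n / g_s (CO2 supply function with the H2O:CO2 diffusivity
  ratio, C_a = 400 umol mol-1), floored at 5, keeping A_n, g_s and C_i
  mutually coherent.
* E = g_s * VPD / P_atm in mmol m-2 s-1; psi_midday = psi_predawn - E/K_plant
  and psi_stem = psi_midday + E/K_leaf, so the evaporative-flux equations
  recover the configured conductances exactly when measurement noise is off.
* Morphology, SPAD, PhiPSII, biomass from genotype-level normals.

Measurement noise is optional and off by default, separating algorithm
verification (exact oracles) from robustness testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantgen import N_REPLICATES_STD_DEFAULT, VarianceComponents, phenotypic_variance

__all__ = ["SimulationConfig", "GroundTruth", "simulate_trial", "truth_variance_components"]

C_A = 400.0  # ambient CO2, umol mol-1
P_ATM_KPA = 101.325
PPFD_GRID = (0.0, 250.0, 500.0, 1000.0, 1500.0, 2000.0)


class ConfigError(ValueError):
    """A simulation-config invariant is violated."""


@dataclass
class SimulationConfig:
    """Study-design and generative parameters for one synthetic trial."""

    n_genotypes: int = 89
    n_replicates: int = 3
    replicate_overrides: dict = field(default_factory=dict)  # genotype_id -> n
    seed: int = 0
    # gas exchange
    A_max: float = 45.0  # umol m-2 s-1, asymptotic assimilation
    K_half: float = 0.12  # mol m-2 s-1, g_s at half-saturation
    gs_base: float = 0.20  # mol m-2 s-1, WW median g_s
    sigma_g: float = 0.22  # SD of genotype effect on log g_s
    sigma_gxt: float = 0.13  # SD of genotype x treatment effect on log g_s
    sigma_e: float = 0.18  # SD of replicate residual on log g_s
    pc_sigma_g: float = 0.12  # SD of genotypic log capacity multiplier
    ws_gs_factor: float = 0.35  # multiplicative WS effect on median g_s
    ws_capacity_factor: float | np.ndarray = 1.0  # WS capacity retention (per genotype)
    vpd_kPa: float = 2.0
    # hydraulics
    psi_predawn_WW: float = -0.15  # MPa
    psi_predawn_WS: float = -0.70  # MPa
    K_plant_base: float = 4.0  # mmol m-2 s-1 MPa-1
    K_leaf_fraction: float = 0.4  # leaf share of whole-pathway resistance
    k_sigma_g: float = 0.20  # genotype lognormal SD on K_plant
    ws_kplant_factor: float = 0.6  # multiplicative WS effect on K_plant
    # haplotype labels
    aquaporins: tuple = ("SbPIP1.1", "SbTIP3.2")
    nrp_fraction: float = 0.4
    haplotype_effect: float = 0.0  # additive shift on log g_s for the NRP
    effect_aquaporin: str = "SbPIP1.1"  # subset of this aquaporin
    # optional extras
    light_response: bool = False
    measurement_noise: bool = False
    an_noise_sd: float = 0.8
    psi_noise_sd: float = 0.02
    spad_noise_sd: float = 1.5

    def validate(self) -> "SimulationConfig":
        if self.n_genotypes < 1 or self.n_replicates < 1:
            raise ConfigError("n_genotypes and n_replicates must be >= 1")
        for name in ("sigma_g", "sigma_gxt", "sigma_e", "pc_sigma_g", "k_sigma_g"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.ws_gs_factor <= 1:
            raise ConfigError("ws_gs_factor must be in (0, 1]")
        if not 0 < self.K_leaf_fraction < 1:
            raise ConfigError("K_leaf_fraction must be in (0, 1)")
        if self.gs_base <= 0 or self.A_max <= 0 or self.K_half <= 0:
            raise ConfigError("gs_base, A_max, K_half must be > 0")
        wcf = np.atleast_1d(np.asarray(self.ws_capacity_factor, dtype=float))
        if wcf.size not in (1, self.n_genotypes):
            raise ConfigError(
                "ws_capacity_factor must be a scalar or one value per genotype"
            )
        if np.any(wcf <= 0):
            raise ConfigError("ws_capacity_factor must be > 0")
        return self

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["ws_capacity_factor"] = np.atleast_1d(
            np.asarray(self.ws_capacity_factor, dtype=float)
        ).tolist()
        d["aquaporins"] = list(self.aquaporins)
        return json.dumps(d, sort_keys=True)


@dataclass
class GroundTruth:
    """Every sampled effect behind one simulated trial."""

    config: SimulationConfig
    seed: int
    genotype_ids: list
    genotype_effects: np.ndarray  # (G,) on log g_s
    gxt_effects: np.ndarray  # (G, 2), columns ordered (WW, WS)
    residuals: np.ndarray  # per record, on log g_s, in record order
    pc_effects: np.ndarray  # (G,) log capacity multiplier
    capacity_ws_factors: np.ndarray  # (G,)
    K_plant: np.ndarray  # (G, 2) configured conductances, (WW, WS)
    K_leaf: np.ndarray  # (G, 2)
    haplotypes: pd.DataFrame  # genotype_id, aquaporin_id, group

    def realized_components(self, trait: str = "log_gs") -> dict:
        if trait == "log_gs":
            return {
                "sigma2_g": float(np.var(self.genotype_effects, ddof=1)),
                "sigma2_gxt": float(np.var(self.gxt_effects.ravel(), ddof=1)),
                "sigma2_e": float(np.var(self.residuals, ddof=1)),
            }
        if trait == "log_capacity":
            return {
                "sigma2_g": float(np.var(self.pc_effects, ddof=1)),
                "sigma2_gxt": 0.0,
                "sigma2_e": 0.0,
            }
        raise ValueError(
            f"trait {trait!r} has no additive generative structure; "
            "supported: 'log_gs', 'log_capacity'"
        )

    def to_sidecar_csv(self, path) -> None:
        """Long CSV of all effect vectors plus a config echo in the header."""
        rows = []
        for i, gid in enumerate(self.genotype_ids):
            rows.append(
                {
                    "genotype_id": gid,
                    "genotype_effect": self.genotype_effects[i],
                    "gxt_effect_WW": self.gxt_effects[i, 0],
                    "gxt_effect_WS": self.gxt_effects[i, 1],
                    "pc_effect": self.pc_effects[i],
                    "capacity_ws_factor": self.capacity_ws_factors[i],
                    "K_plant_WW": self.K_plant[i, 0],
                    "K_plant_WS": self.K_plant[i, 1],
                    "K_leaf_WW": self.K_leaf[i, 0],
                    "K_leaf_WS": self.K_leaf[i, 1],
                }
            )
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n# config={self.config.to_json()}\n")
            pd.DataFrame(rows).to_csv(fh, index=False)


def truth_variance_components(
    truth: GroundTruth,
    trait: str = "log_gs",
    n_replicates_std: float = N_REPLICATES_STD_DEFAULT,
) -> VarianceComponents:
    """Realized (sample) variance components of the stored effect vectors.

    These are the *drawn* effects' variances, not the asymptotic parameters —
    the correct oracle for single-trial parameter-recovery tests.
    """
    comps = truth.realized_components(trait)
    s2p = phenotypic_variance(
        comps["sigma2_g"], comps["sigma2_gxt"], comps["sigma2_e"], 2, n_replicates_std
    )
    return VarianceComponents(
        trait=trait,
        sigma2_g=comps["sigma2_g"],
        sigma2_gxt=comps["sigma2_gxt"],
        sigma2_e=comps["sigma2_e"],
        sigma2_p=s2p,
        n_treatments=2,
        n_replicates_std=n_replicates_std,
        convention="realized",
    )


def _light_response_json(e_at_2000: float) -> str:
    scale = e_at_2000 / (2000.0 / 2300.0)
    pairs = [[p, scale * p / (p + 300.0)] for p in PPFD_GRID]
    return json.dumps([[p, round(e, 6)] for p, e in pairs])


def simulate_trial(config: SimulationConfig | None = None, seed: int | None = None):
    """Generate one replicate-level trial table and its ground truth.

    Returns ``(records, truth)`` where ``records`` is a canonical long-format
    DataFrame (same schema as :mod:`sorghum_iwue.io`) and ``truth`` a
    :class:`GroundTruth`. Same seed implies bit-identical output.
    """
    cfg = (config or SimulationConfig()).validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    G = cfg.n_genotypes
    gids = [f"G{i + 1:03d}" for i in range(G)]
    reps = np.array([cfg.replicate_overrides.get(g, cfg.n_replicates) for g in gids])

    # -- effect draws, fixed order --------------------------------------------
    g_eff = rng.normal(0.0, cfg.sigma_g, size=G)
    gxt_eff = rng.normal(0.0, cfg.sigma_gxt, size=(G, 2))
    pc_eff = rng.normal(0.0, cfg.pc_sigma_g, size=G)
    k_mult = np.exp(rng.normal(0.0, cfg.k_sigma_g, size=G))
    n_rows = int(reps.sum()) * 2
    residuals = rng.normal(0.0, cfg.sigma_e, size=n_rows)

    # genotype-level morphology / pigments
    spad_g = rng.normal(42.0, 6.0, size=G)
    leaf_width_g = np.clip(rng.normal(4.5, 0.7, size=G), 1.5, None)
    leaf_length_g = np.clip(rng.normal(70.0, 10.0, size=G), 20.0, None)
    leaf_thickness_g = np.clip(rng.normal(0.25, 0.03, size=G), 0.1, None)
    lma_g = np.clip(rng.normal(30.0, 5.0, size=G), 10.0, None)
    rwc_dev_g = rng.normal(0.0, 0.03, size=G)
    biomass_g = np.exp(rng.normal(np.log(25.0), 0.45, size=G))

    # haplotype labels
    hap_rows = []
    nrp_mask = {}
    for aqp in cfg.aquaporins:
        is_nrp = rng.random(G) < cfg.nrp_fraction
        nrp_mask[aqp] = is_nrp
        for gid, flag in zip(gids, is_nrp):
            hap_rows.append(
                {"genotype_id": gid, "aquaporin_id": aqp, "group": "NRP" if flag else "RP"}
            )
    haplotypes = pd.DataFrame(hap_rows)
    hap_shift = np.zeros(G)
    if cfg.haplotype_effect != 0.0 and cfg.effect_aquaporin in nrp_mask:
        hap_shift = np.where(nrp_mask[cfg.effect_aquaporin], cfg.haplotype_effect, 0.0)

    wcf = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.ws_capacity_factor, dtype=float)), (G,)
    ).copy()

    # configured conductances per genotype x treatment (WW, WS)
    K_plant = np.column_stack(
        [cfg.K_plant_base * k_mult, cfg.K_plant_base * k_mult * cfg.ws_kplant_factor]
    )
    K_leaf = K_plant / cfg.K_leaf_fraction

    # -- assemble rows: genotype-major, treatment (WW then WS), replicate ----
    treatments = ("WW", "WS")
    rec = {c: [] for c in ("genotype_id", "treatment", "replicate")}
    gi_idx, ti_idx = [], []
    for i in range(G):
        for t_i, trt in enumerate(treatments):
            for r in range(reps[i]):
                rec["genotype_id"].append(gids[i])
                rec["treatment"].append(trt)
                rec["replicate"].append(r + 1)
                gi_idx.append(i)
                ti_idx.append(t_i)
    gi = np.array(gi_idx)
    ti = np.array(ti_idx)
    ws = ti == 1

    log_gs = (
        np.log(cfg.gs_base)
        + np.where(ws, np.log(cfg.ws_gs_factor), 0.0)
        + g_eff[gi]
        + hap_shift[gi]
        + gxt_eff[gi, ti]
        + residuals
    )
    gs = np.exp(log_gs)
    capacity = np.exp(pc_eff[gi]) * np.where(ws, wcf[gi], 1.0)
    A_n = capacity * cfg.A_max * gs / (gs + cfg.K_half)
    if cfg.measurement_noise:
        A_n = A_n + rng.normal(0.0, cfg.an_noise_sd, size=n_rows)
    C_i = np.maximum(C_A - 1.6 * A_n / gs, 5.0)
    E = gs * cfg.vpd_kPa / P_ATM_KPA * 1000.0  # mmol m-2 s-1

    psi_pd = np.where(ws, cfg.psi_predawn_WS, cfg.psi_predawn_WW)
    kp = K_plant[gi, ti]
    kl = K_leaf[gi, ti]
    psi_md = psi_pd - E / kp
    psi_stem = psi_md + E / kl
    if cfg.measurement_noise:
        psi_md = psi_md + rng.normal(0.0, cfg.psi_noise_sd, size=n_rows)
        psi_stem = psi_stem + rng.normal(0.0, cfg.psi_noise_sd, size=n_rows)

    spad = spad_g[gi] - np.where(ws, 6.0, 0.0)
    if cfg.measurement_noise:
        spad = spad + rng.normal(0.0, cfg.spad_noise_sd, size=n_rows)
    phi = np.clip(np.where(ws, 0.30, 0.45) + 0.5 * pc_eff[gi], 0.02, 0.95)

    disc_area = 1.5e-4  # three 0.5 cm2 discs, m2
    lma = lma_g[gi] * np.where(ws, 1.15, 1.0)
    disc_dw = lma * disc_area
    disc_tw = disc_dw * 2.5
    rwc = np.clip(np.where(ws, 0.70, 0.85) + rwc_dev_g[gi], 0.30, 0.98)
    disc_fw = disc_dw + rwc * (disc_tw - disc_dw)
    biomass = biomass_g[gi] * np.where(ws, 0.45, 1.0)

    records = pd.DataFrame(
        {
            **rec,
            "A_n": A_n,
            "g_s": gs,
            "C_i": C_i,
            "E": E,
            "psi_predawn": psi_pd,
            "psi_stem": psi_stem,
            "psi_midday": psi_md,
            "SPAD": spad,
            "phi_PSII": phi,
            "leaf_width": leaf_width_g[gi],
            "leaf_length": leaf_length_g[gi],
            "leaf_thickness": leaf_thickness_g[gi],
            "disc_FW": disc_fw,
            "disc_TW": disc_tw,
            "disc_DW": disc_dw,
            "disc_area": disc_area,
            "biomass": biomass,
        }
    )
    if cfg.light_response:
        records["light_response"] = [_light_response_json(e) for e in E]

    truth = GroundTruth(
        config=cfg,
        seed=seed,
        genotype_ids=gids,
        genotype_effects=g_eff,
        gxt_effects=gxt_eff,
        residuals=residuals,
        pc_effects=pc_eff,
        capacity_ws_factors=wcf,
        K_plant=K_plant,
        K_leaf=K_leaf,
        haplotypes=haplotypes,
    )
    return records, truth
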