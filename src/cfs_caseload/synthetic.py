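"""Seedable synthetic hazard tables and product registries.

No machine-readable deposit of the underlying hazard report or of the
German product register exists, so this module generates inputs with
the same statistical structure: ~378 approved substances spread over
the documented use categories, a quarter of them hazard-flagged; ~1,378
products composed of 1-3 substances; and authorised uses drawn from a
long-tailed crop x pest popularity distribution (uses per product:
median ~6, mean ~13, max a few hundred).

Substances are given *latent* hazard states first (which PBT route, if
any; which classification labels; isomer flag), and numeric endpoints
are then sampled from log-normals truncated to be consistent with the
latent state.  The classifier therefore reproduces the latent rates
through its actual threshold logic rather than being handed answers.

Every stage draws from its own named substream of the seed, so adding
products does not change substance draws and vice versa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import norm

from .errors import ConfigError
from .registry import (
    HazardProfile,
    Product,
    Registry,
    SubstanceRecord,
    UseKey,
)

_STAGES = {"latent": 0, "substances": 1, "endpoints": 2,
           "products": 3, "pool": 4, "uses": 5}

_MAIN_CATEGORIES = ("AC", "FU", "HB", "IN", "PG", "RE", "RO", "OTHER")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGES[stage]])


@dataclass(frozen=True)
class EndpointModel:
    """Log-normal endpoint model: location/scale on the log scale plus a
    missingness probability."""
    mu: float
    sigma: float
    p_missing: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigError(f"endpoint sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.p_missing <= 1.0:
            raise ConfigError(f"p_missing must be in [0, 1], got {self.p_missing}")


def _default_endpoint_models() -> Dict[str, EndpointModel]:
    ln = math.log
    return {
        # degradation half-lives, days
        "dt50_water": EndpointModel(ln(8.0), 1.0, 0.25),
        "dt50_sediment": EndpointModel(ln(30.0), 1.0, 0.35),
        "dt50_soil": EndpointModel(ln(20.0), 1.0, 0.05),
        # bioconcentration factor, L/kg
        "bcf": EndpointModel(ln(80.0), 1.3, 0.30),
        # chronic NOECs, mg/L
        "noec_fish": EndpointModel(ln(1.0), 1.5, 0.10),
        "noec_daphnia": EndpointModel(ln(1.0), 1.5, 0.15),
        "noec_algae": EndpointModel(ln(1.0), 1.5, 0.15),
        "noec_other": EndpointModel(ln(1.0), 1.5, 0.60),
    }


def _default_class_label_probs() -> Dict[str, Dict[str, float]]:
    return {
        "carc": {"2": 0.04},
        "muta": {},
        "repro_existing": {"1A": 0.004, "1B": 0.012, "2": 0.05},
        "repro_forthcoming": {"1B": 0.008, "2": 0.02},
        "stot_re": {"1": 0.01, "2": 0.05},
    }


def _default_category_weights() -> Dict[str, float]:
    # marginal counts of the 378 approved substances per use category
    return {"AC": 8, "FU": 103, "HB": 110, "IN": 55, "PG": 25,
            "RE": 17, "RO": 5, "OTHER": 14, "MULTI": 35, "NONE": 6}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic scenario; same seed, same output.

    Defaults are the German-market-like preset: 378 substances, 1,378
    products, 309 crops x 477 pests, calibrated so the classifier finds
    ~26% CFS and ~25% candidate products covering ~half of all uses.
    """

    seed: int = 2013
    # substances
    n_substances: int = 378
    category_weights: Dict[str, float] = field(default_factory=_default_category_weights)
    multi_k_probs: Dict[int, float] = field(default_factory=lambda: {2: 0.8, 3: 0.2})
    biopesticide_prob: float = 0.08
    # latent hazard structure
    c2_route_probs: Dict[str, float] = field(
        default_factory=lambda: {"env": 57 / 378, "both": 13 / 378, "human": 7 / 378})
    persistence_prob: float = 0.85     # P flag among PBT substances
    bioaccumulation_prob: float = 0.35  # B flag among PBT substances
    class_label_probs: Dict[str, Dict[str, float]] = field(
        default_factory=_default_class_label_probs)
    endocrine_pair_prob: float = 7 / 378
    isomer_flag_prob: float = 2 / 378
    # human reference doses: one latent log-potency per substance with
    # correlated ADI/ARfD/AOEL around it; PBT substances are shifted
    # toward lower doses so the percentile criterion overlaps PBT.
    dose_latent_mu: float = math.log(0.02)
    dose_latent_sigma: float = 1.5
    dose_noise_sigma: float = 0.2
    arfd_offset: float = 1.0
    aoel_offset: float = 0.3
    c2_dose_shift: float = -2.5
    dose_missing: Dict[str, float] = field(
        default_factory=lambda: {"adi": 0.05, "arfd": 0.35, "aoel": 0.10})
    endpoint_models: Dict[str, EndpointModel] = field(
        default_factory=_default_endpoint_models)
    # thresholds the endpoint sampler respects (kept equal to the
    # classifier defaults so latent flags survive the threshold path)
    dt50_thresholds: Dict[str, float] = field(
        default_factory=lambda: {"dt50_water": 60.0, "dt50_sediment": 180.0,
                                 "dt50_soil": 120.0})
    bcf_limit: float = 2000.0
    noec_limit: float = 0.01
    # registry
    n_products: int = 1378
    substances_per_product: Dict[int, float] = field(
        default_factory=lambda: {1: 0.85, 2: 0.13, 3: 0.02})
    # products concentrate on substances with broad use spectra; hazard-
    # latent substances carry the configured market-weight penalty
    substance_popularity_skew: float = 0.31
    cfs_market_weight: float = 0.82
    n_crops: int = 309
    n_pests: int = 477
    crop_skew: float = 0.8
    pest_skew: float = 0.8
    # uses attach to active substances: each substance has a "territory"
    # (its authorised use spectrum, a heavy-tailed size) and a product
    # covers a large random fraction of its substances' territories.
    # Territories overlap at the edges and all products occasionally
    # draw from a small popular core, which is what creates uses shared
    # across substances and hence alternative products.
    territory_median: float = 4.1
    territory_sigma: float = 1.23
    territory_overlap_frac: float = 0.08
    cfs_territory_boost: float = 1.0
    core_size: int = 150
    core_frac: float = 0.05
    core_skew: float = 0.4
    within_territory_skew: float = 0.9
    product_fill_min: float = 0.7
    product_fill_max: float = 1.0
    # a product is formulated for its primary substance's spectrum;
    # co-formulated substances contribute only a partial slice of theirs
    secondary_fill: float = 0.2
    max_uses_per_product: int = 340

    def __post_init__(self):
        if self.n_substances < 1 or self.n_products < 1:
            raise ConfigError("n_substances and n_products must be >= 1")
        if self.n_crops < 1 or self.n_pests < 1:
            raise ConfigError("n_crops and n_pests must be >= 1")
        probs = [self.biopesticide_prob, self.endocrine_pair_prob,
                 self.isomer_flag_prob, self.persistence_prob,
                 self.bioaccumulation_prob]
        probs += list(self.c2_route_probs.values())
        for block in self.class_label_probs.values():
            probs += list(block.values())
        probs += list(self.dose_missing.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if sum(self.c2_route_probs.values()) > 1.0:
            raise ConfigError("c2 route probabilities sum to more than 1")
        if any(w < 0 for w in self.category_weights.values()):
            raise ConfigError("category weights must be non-negative")
        if not 0.0 <= self.territory_overlap_frac < 1.0:
            raise ConfigError("territory_overlap_frac must be in [0, 1)")
        if not 0.0 <= self.core_frac <= 1.0:
            raise ConfigError("core_frac must be in [0, 1]")
        if self.territory_median < 1 or self.territory_sigma <= 0:
            raise ConfigError("territory size distribution is degenerate")
        if not 0.0 < self.product_fill_min <= self.product_fill_max <= 1.0:
            raise ConfigError("product fill fractions must satisfy "
                              "0 < min <= max <= 1")
        if not 0.0 <= self.secondary_fill <= 1.0:
            raise ConfigError("secondary_fill must be in [0, 1]")
        if self.max_uses_per_product < 1:
            raise ConfigError("max_uses_per_product must be >= 1")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "n_substances": self.n_substances,
            "category_weights": dict(self.category_weights),
            "multi_k_probs": {int(k): v for k, v in self.multi_k_probs.items()},
            "biopesticide_prob": self.biopesticide_prob,
            "c2_route_probs": dict(self.c2_route_probs),
            "persistence_prob": self.persistence_prob,
            "bioaccumulation_prob": self.bioaccumulation_prob,
            "class_label_probs": {k: dict(v) for k, v in self.class_label_probs.items()},
            "endocrine_pair_prob": self.endocrine_pair_prob,
            "isomer_flag_prob": self.isomer_flag_prob,
            "dose_latent_mu": self.dose_latent_mu,
            "dose_latent_sigma": self.dose_latent_sigma,
            "dose_noise_sigma": self.dose_noise_sigma,
            "arfd_offset": self.arfd_offset,
            "aoel_offset": self.aoel_offset,
            "c2_dose_shift": self.c2_dose_shift,
            "dose_missing": dict(self.dose_missing),
            "endpoint_models": {k: [m.mu, m.sigma, m.p_missing]
                                for k, m in self.endpoint_models.items()},
            "dt50_thresholds": dict(self.dt50_thresholds),
            "bcf_limit": self.bcf_limit,
            "noec_limit": self.noec_limit,
            "n_products": self.n_products,
            "substances_per_product": {int(k): v for k, v in
                                       self.substances_per_product.items()},
            "substance_popularity_skew": self.substance_popularity_skew,
            "cfs_market_weight": self.cfs_market_weight,
            "n_crops": self.n_crops,
            "n_pests": self.n_pests,
            "crop_skew": self.crop_skew,
            "pest_skew": self.pest_skew,
            "territory_median": self.territory_median,
            "territory_sigma": self.territory_sigma,
            "territory_overlap_frac": self.territory_overlap_frac,
            "cfs_territory_boost": self.cfs_territory_boost,
            "core_size": self.core_size,
            "core_frac": self.core_frac,
            "core_skew": self.core_skew,
            "within_territory_skew": self.within_territory_skew,
            "product_fill_min": self.product_fill_min,
            "product_fill_max": self.product_fill_max,
            "secondary_fill": self.secondary_fill,
            "max_uses_per_product": self.max_uses_per_product,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "endpoint_models" in d:
            d["endpoint_models"] = {
                k: EndpointModel(*v) for k, v in d["endpoint_models"].items()}
        if "multi_k_probs" in d:
            d["multi_k_probs"] = {int(k): v for k, v in d["multi_k_probs"].items()}
        if "substances_per_product" in d:
            d["substances_per_product"] = {
                int(k): v for k, v in d["substances_per_product"].items()}
        return cls(**d)


def german_like_preset(seed: int = 2013) -> ScenarioConfig:
    """The documented default scenario emulating the German market.

    378 substances, 1,378 products, a 309-crop x 477-pest vocabulary,
    long-tailed uses per product, and hazard rates calibrated so the
    classifier identifies ~26% of substances as CFS and ~25% of
    products as candidates.  The default seed (2013, the reference year
    of the emulated data) is fixed so the preset is reproducible.
    """
    return ScenarioConfig(seed=seed)


def small_preset(seed: int = 0) -> ScenarioConfig:
    """A fast, structurally identical scenario for tests and examples."""
    return ScenarioConfig(
        seed=seed,
        n_substances=60,
        n_products=50,
        n_crops=25,
        n_pests=30,
        territory_median=4.0,
        territory_sigma=0.9,
        core_size=20,
        max_uses_per_product=40,
    )


# ---------------------------------------------------------------------------
# latent hazard state


def _draw_label(u: float, probs: Dict[str, float]) -> str:
    acc = 0.0
    for label, p in probs.items():
        acc += p
        if u < acc:
            return label
    return "none"


_T_HUMAN_DEFAULT = frozenset({"1A", "1B", "2"})


def _labels_qualify_t_human(carc, muta, rex, rfc, stot) -> bool:
    return (any(c in _T_HUMAN_DEFAULT for c in (carc, muta, rex, rfc))
            or stot in ("1", "2"))


@dataclass
class _LatentState:
    route: np.ndarray        # 0 none, 1 env, 2 both, 3 human
    p_flag: np.ndarray
    b_flag: np.ndarray
    carc: List[str]
    muta: List[str]
    repro_existing: List[str]
    repro_forthcoming: List[str]
    stot: List[str]
    isomer: np.ndarray
    latent_cfs: np.ndarray   # CFS through any non-percentile criterion


def _latent_hazard(cfg: ScenarioConfig) -> _LatentState:
    """Draw the latent hazard state of every substance.

    Drawn from the dedicated "latent" substream so that both the hazard
    generator and the registry generator can reconstruct it identically.
    """
    rng = _stage_rng(cfg.seed, "latent")
    n = cfg.n_substances
    route = np.zeros(n, dtype=int)
    p_flag = np.zeros(n, dtype=bool)
    b_flag = np.zeros(n, dtype=bool)
    carc: List[str] = []
    muta: List[str] = []
    rex: List[str] = []
    rfc: List[str] = []
    stot: List[str] = []
    isomer = np.zeros(n, dtype=bool)

    route_codes = {"env": 1, "both": 2, "human": 3}
    lp = cfg.class_label_probs
    for i in range(n):
        r = _draw_label(rng.random(), {k: v for k, v in cfg.c2_route_probs.items()})
        route[i] = route_codes.get(r, 0)
        if route[i]:
            p = rng.random() < cfg.persistence_prob
            b = rng.random() < cfg.bioaccumulation_prob
            if not p and not b:
                p = True
            p_flag[i], b_flag[i] = p, b
        ca = _draw_label(rng.random(), lp.get("carc", {}))
        mu = _draw_label(rng.random(), lp.get("muta", {}))
        re = _draw_label(rng.random(), lp.get("repro_existing", {}))
        rf = _draw_label(rng.random(), lp.get("repro_forthcoming", {}))
        st = _draw_label(rng.random(), lp.get("stot_re", {}))
        if rng.random() < cfg.endocrine_pair_prob:
            ca, re = "2", "2"
        # substances on the human PBT route must carry a qualifying label
        if route[i] in (2, 3) and not _labels_qualify_t_human(ca, mu, re, rf, st):
            st = "2"
        isomer[i] = rng.random() < cfg.isomer_flag_prob
        carc.append(ca)
        muta.append(mu)
        rex.append(re)
        rfc.append(rf)
        stot.append(st)

    sev = {"none": 0, "2": 1, "1B": 2, "1A": 3}
    c6 = np.array([rex[i] in ("1A", "1B") or rfc[i] in ("1A", "1B")
                   for i in range(n)])
    c7 = np.array([carc[i] == "2"
                   and max(rex[i], rfc[i], key=sev.__getitem__) == "2"
                   for i in range(n)])
    latent_cfs = (route > 0) | c6 | c7 | isomer
    return _LatentState(route, p_flag, b_flag, carc, muta, rex, rfc, stot,
                        isomer, latent_cfs)


# ---------------------------------------------------------------------------
# hazard generation


def _trunc_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                     lower: Optional[float] = None,
                     upper: Optional[float] = None) -> float:
    """One draw from a log-normal truncated to (lower, upper)."""
    lo = 0.0 if lower is None else float(norm.cdf((math.log(lower) - mu) / sigma))
    hi = 1.0 if upper is None else float(norm.cdf((math.log(upper) - mu) / sigma))
    u = rng.uniform(lo, hi)
    u = min(max(u, 1e-12), 1.0 - 1e-12)
    return math.exp(mu + sigma * float(norm.ppf(u)))


def _substance_id(i: int) -> str:
    return f"S{i + 1:04d}"


def gen_hazard_profiles(cfg: ScenarioConfig,
                        ) -> Tuple[List[SubstanceRecord], List[HazardProfile]]:
    """Generate the substance table and the hazard table.

    Endpoint values are drawn from truncated log-normals consistent
    with each substance's latent hazard state; classification labels
    come from the latent state directly.  Reproducible under the seed.
    """
    latent = _latent_hazard(cfg)
    n = cfg.n_substances

    # --- substance records (categories, aliases) -----------------------
    rng_s = _stage_rng(cfg.seed, "substances")
    cat_names = list(cfg.category_weights)
    cat_w = np.array([cfg.category_weights[c] for c in cat_names], dtype=float)
    cat_w = cat_w / cat_w.sum()
    main_w = np.array([cfg.category_weights.get(c, 0.0) for c in _MAIN_CATEGORIES],
                      dtype=float)
    main_w = main_w / main_w.sum()
    multi_ks = sorted(cfg.multi_k_probs)
    multi_kw = np.array([cfg.multi_k_probs[k] for k in multi_ks], dtype=float)
    multi_kw = multi_kw / multi_kw.sum()

    records: List[SubstanceRecord] = []
    for i in range(n):
        cat = cat_names[int(rng_s.choice(len(cat_names), p=cat_w))]
        if cat == "NONE":
            categories: frozenset = frozenset()
        elif cat == "MULTI":
            k = int(multi_ks[int(rng_s.choice(len(multi_ks), p=multi_kw))])
            chosen = rng_s.choice(len(_MAIN_CATEGORIES), size=k,
                                  replace=False, p=main_w)
            categories = frozenset(_MAIN_CATEGORIES[j] for j in chosen)
        else:
            categories = frozenset({cat})
        sid = _substance_id(i)
        records.append(SubstanceRecord(
            substance_id=sid,
            aliases=frozenset({f"as-{i + 1:04d}"}),
            use_categories=categories,
            is_biopesticide=bool(rng_s.random() < cfg.biopesticide_prob),
        ))

    # --- numeric endpoints ---------------------------------------------
    rng_e = _stage_rng(cfg.seed, "endpoints")
    em = cfg.endpoint_models
    dt_names = ("dt50_water", "dt50_sediment", "dt50_soil")
    profiles: List[HazardProfile] = []
    for i in range(n):
        is_c2 = latent.route[i] > 0
        t_aqua = latent.route[i] in (1, 2)

        # human reference doses around one latent log-potency
        z = rng_e.normal(cfg.dose_latent_mu, cfg.dose_latent_sigma)
        if is_c2:
            z += cfg.c2_dose_shift
        doses: Dict[str, Optional[float]] = {}
        for name, offset in (("adi", 0.0), ("arfd", cfg.arfd_offset),
                             ("aoel", cfg.aoel_offset)):
            v = math.exp(z + offset + rng_e.normal(0.0, cfg.dose_noise_sigma))
            doses[name] = None if rng_e.random() < cfg.dose_missing[name] else v

        # half-lives
        dt: Dict[str, Optional[float]] = {}
        if is_c2 and latent.p_flag[i]:
            forced = dt_names[int(rng_e.choice(3, p=[0.25, 0.25, 0.5]))]
        else:
            forced = None
        for name in dt_names:
            m = em[name]
            thr = cfg.dt50_thresholds[name]
            if name == forced:
                # above its threshold; shifted location keeps values plausible
                dt[name] = _trunc_lognormal(rng_e, math.log(thr * 2.0),
                                            m.sigma, lower=thr)
                continue
            v = _trunc_lognormal(rng_e, m.mu, m.sigma, upper=thr)
            dt[name] = None if rng_e.random() < m.p_missing else v

        # bioconcentration
        m = em["bcf"]
        if is_c2 and latent.b_flag[i]:
            bcf: Optional[float] = _trunc_lognormal(
                rng_e, math.log(cfg.bcf_limit * 2.5), 0.8, lower=cfg.bcf_limit)
        else:
            v = _trunc_lognormal(rng_e, m.mu, m.sigma, upper=cfg.bcf_limit)
            bcf = None if rng_e.random() < m.p_missing else v

        # chronic NOECs
        noec_names = ("noec_fish", "noec_daphnia", "noec_algae", "noec_other")
        noecs: Dict[str, Optional[float]] = {}
        if t_aqua:
            forced_taxon = noec_names[int(rng_e.choice(4, p=[0.3, 0.4, 0.3, 0.0]))]
        else:
            forced_taxon = None
        for name in noec_names:
            m = em[name]
            if name == forced_taxon:
                noecs[name] = _trunc_lognormal(
                    rng_e, math.log(cfg.noec_limit / 4.0), m.sigma,
                    upper=cfg.noec_limit)
                continue
            v = _trunc_lognormal(rng_e, m.mu, m.sigma, lower=cfg.noec_limit)
            noecs[name] = None if rng_e.random() < m.p_missing else v

        profiles.append(HazardProfile(
            substance_id=_substance_id(i),
            adi=doses["adi"], arfd=doses["arfd"], aoel=doses["aoel"],
            dt50_water=dt["dt50_water"], dt50_sediment=dt["dt50_sediment"],
            dt50_soil=dt["dt50_soil"],
            bcf=bcf,
            noec_fish=noecs["noec_fish"], noec_daphnia=noecs["noec_daphnia"],
            noec_algae=noecs["noec_algae"], noec_other=noecs["noec_other"],
            carc_class=latent.carc[i], muta_class=latent.muta[i],
            repro_class_existing=latent.repro_existing[i],
            repro_class_forthcoming=latent.repro_forthcoming[i],
            stot_re_class=latent.stot[i],
            nonactive_isomer_flag=bool(latent.isomer[i]),
        ))
    return records, profiles


# ---------------------------------------------------------------------------
# registry generation


def _weighted_top_k(rng: np.random.Generator, weights: np.ndarray,
                    k: int) -> np.ndarray:
    """Weighted sampling without replacement via Gumbel top-k."""
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.size)
    if k >= weights.size:
        return np.argsort(-keys)
    idx = np.argpartition(-keys, k)[:k]
    return idx

def gen_registry(cfg: ScenarioConfig,
                 substances: List[SubstanceRecord]) -> Registry:
    """Generate a product registry over the given substance table.

    Every substance draws a *territory* — the set of crop x pest uses
    for which its products can be authorised — with a heavy-tailed
    size.  Products cover a large random fraction of their substances'
    territories, so products of the same substance share most uses.
    Territories overlap their (randomly assigned) neighbours at the
    edges, and every product draws a few uses from a small popular
    core; both mechanisms create uses shared across substances, which
    is where alternative products come from.  When the substance table
    is the one this config generates, hazard-latent substances receive
    the configured market-weight penalty (CFS are rarer in products)
    and the territory boost (candidate products have broader use
    spectra).
    """
    if not substances:
        raise ConfigError("substance table must be non-empty")
    n_sub = len(substances)
    if n_sub == cfg.n_substances:
        latent_cfs = _latent_hazard(cfg).latent_cfs
    else:
        latent_cfs = np.zeros(n_sub, dtype=bool)

    # --- territories over the crop x pest pool --------------------------
    rng_pool = _stage_rng(cfg.seed, "pool")
    # stratified (Latin-hypercube) log-normal draw, separately within the
    # hazard-latent and ordinary groups: every realisation reproduces the
    # size distribution including its tail, rather than a tail lottery
    t_raw = np.empty(n_sub)
    for mask in (latent_cfs, ~latent_cfs):
        m = int(mask.sum())
        if m == 0:
            continue
        u = (rng_pool.permutation(m) + rng_pool.uniform(size=m)) / m
        u = np.clip(u, 1e-9, 1.0 - 1e-9)
        t_raw[mask] = np.exp(math.log(cfg.territory_median)
                             + cfg.territory_sigma * norm.ppf(u))
    t_raw[latent_cfs] *= cfg.cfs_territory_boost
    sizes = np.clip(np.round(t_raw), 1, cfg.max_uses_per_product).astype(int)
    order = rng_pool.permutation(n_sub)
    overlap = np.floor(sizes * cfg.territory_overlap_frac).astype(int)
    starts = np.zeros(n_sub, dtype=int)
    prev_end = cfg.core_size
    for i in order:
        start = max(cfg.core_size, prev_end - int(overlap[i]))
        starts[i] = start
        prev_end = start + int(sizes[i])
    pool_needed = prev_end
    if pool_needed > cfg.n_crops * cfg.n_pests:
        raise ConfigError(
            f"scenario needs {pool_needed} distinct uses but only "
            f"{cfg.n_crops * cfg.n_pests} crop x pest pairs exist")
    pool = _build_pool(rng_pool, cfg, pool_needed)

    # --- products -------------------------------------------------------
    rng_p = _stage_rng(cfg.seed, "products")
    w = np.power(sizes.astype(float), cfg.substance_popularity_skew)
    w[latent_cfs] *= cfg.cfs_market_weight
    w = w / w.sum()
    ks = sorted(cfg.substances_per_product)
    kw = np.array([cfg.substances_per_product[k] for k in ks], dtype=float)
    kw = kw / kw.sum()

    products: Dict[str, Product] = {}
    member_index: Dict[str, List[int]] = {}
    for j in range(cfg.n_products):
        k = min(int(ks[int(rng_p.choice(len(ks), p=kw))]), n_sub)
        idx = sorted(int(i) for i in _weighted_top_k(rng_p, w, k))
        cats: set = set()
        for i in idx:
            cats |= set(substances[i].use_categories)
        pid = f"P{j + 1:04d}"
        products[pid] = Product(
            product_id=pid,
            name=f"product {j + 1:04d}",
            substance_ids=frozenset(substances[i].substance_id for i in idx),
            product_categories=frozenset(cats) or frozenset({"OTHER"}),
        )
        member_index[pid] = idx

    # --- authorisations -------------------------------------------------
    rng_u = _stage_rng(cfg.seed, "uses")
    core_w = (1.0 / np.power(np.arange(1, cfg.core_size + 1, dtype=float),
                             cfg.core_skew)
              if cfg.core_size else np.empty(0))
    terr_w = {int(i): 1.0 / np.power(np.arange(1, sizes[i] + 1, dtype=float),
                                     cfg.within_territory_skew)
              for i in range(n_sub)}
    cap = cfg.max_uses_per_product
    authorisations: Dict[str, frozenset] = {}
    for pid, idx in member_index.items():
        primary = max(idx, key=lambda i: w[i])
        chosen: set = set()
        for i in idx:
            f = rng_u.uniform(cfg.product_fill_min, cfg.product_fill_max)
            if i != primary:
                f *= cfg.secondary_fill
            k_i = int(round(f * int(sizes[i])))
            if i == primary:
                k_i = max(1, k_i)
            if k_i <= 0:
                continue
            sel = _weighted_top_k(rng_u, terr_w[i], k_i)
            chosen.update(int(starts[i]) + int(r) for r in sel)
        if cfg.core_size and cfg.core_frac > 0:
            # every product keeps a toehold in the shared popular core,
            # so candidates almost always meet some alternative product
            n_core = max(1, int(round(cfg.core_frac * len(chosen))))
            if n_core > 0:
                sel = _weighted_top_k(rng_u, core_w, min(n_core, cfg.core_size))
                chosen.update(int(r) for r in sel)
        slots = sorted(chosen)[:cap]
        authorisations[pid] = frozenset(pool[s] for s in slots)

    return Registry(products=products, authorisations=authorisations)


def _build_pool(rng: np.random.Generator, cfg: ScenarioConfig,
                n_pairs: int) -> List[UseKey]:
    """Distinct crop x pest pairs drawn from skewed crop/pest margins."""
    wc = 1.0 / np.power(np.arange(1, cfg.n_crops + 1), cfg.crop_skew)
    wc /= wc.sum()
    wp = 1.0 / np.power(np.arange(1, cfg.n_pests + 1), cfg.pest_skew)
    wp /= wp.sum()
    pool: List[UseKey] = []
    seen: set = set()
    for _ in range(200):
        if len(pool) >= n_pairs:
            break
        crops = rng.choice(cfg.n_crops, size=2 * n_pairs, p=wc)
        pests = rng.choice(cfg.n_pests, size=2 * n_pairs, p=wp)
        for c, p in zip(crops, pests):
            pair = (int(c), int(p))
            if pair in seen:
                continue
            seen.add(pair)
            pool.append(UseKey(crop=f"crop-{c + 1:03d}",
                               pest=f"pest-{p + 1:03d}"))
            if len(pool) >= n_pairs:
                break
    if len(pool) < n_pairs:
        raise ConfigError(
            f"could not assemble {n_pairs} distinct uses from "
            f"{cfg.n_crops} crops x {cfg.n_pests} pests")
    return pool


def generate_scenario(cfg: ScenarioConfig):
    """Convenience: generate (substances, profiles, registry) in one call."""
    substances, profiles = gen_hazard_profiles(cfg)
    registry = gen_registry(cfg, substances)
    return substances, profiles, registry
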