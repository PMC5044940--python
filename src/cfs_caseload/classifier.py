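"""Candidate-for-substitution (CFS) classification of active substances.

An approved active substance is a CFS when it meets at least one of
seven hazard criteria.  Operationally:

1. Its ADI, ARfD or AOEL is below the q-quantile (default 5%) of the
   substances in one of its use groups, per endpoint.
2. It meets two of the three PBT criteria (persistent, bioaccumulative,
   toxic), where toxicity may be aquatic (chronic NOEC) or human (CMR /
   STOT RE classification).
3. Concern linked to the nature of critical effects — constant false
   here: no approved substance was found to meet it.
4. It contains a significant proportion of non-active isomers.
5. Carcinogen category 1A/1B — constant false here: such substances
   fall under the approval cut-off instead.
6. It is (or is to be) classified toxic for reproduction category
   1A or 1B, merging existing and forthcoming classifications.
7. Interim endocrine-disruption rule: carcinogenic category 2 together
   with reproductive toxicity category 2.

Criteria 1, 6, 7 and the human-toxicity route of criterion 2 flag the
substance for human-health reasons; the aquatic route of criterion 2
and criterion 4 flag it for environmental reasons.  A substance may be
flagged on both bases.

Inputs may carry pre-assessed booleans (P, B, T_aqua, T_human, c1, c4,
c6, c7).  By default these take precedence over raw endpoint values,
because upstream assessments already merged evidence that the raw
table cannot represent; raw thresholds are the fallback path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

from .errors import CaseloadError, ConfigError
from .registry import HazardProfile, SubstanceRecord, USE_CATEGORIES

#: severity order of CLP classes for "merge existing and forthcoming"
_CMR_SEVERITY = {"none": 0, "2": 1, "1B": 2, "1A": 3}

BASES = ("none", "human_only", "env_only", "both")


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable parameters of the CFS rule engine.

    percentile_q
        Quantile used by criterion 1 within each use group (fraction).
    quantile_method
        Empirical quantile rule, any method accepted by
        :func:`numpy.quantile` ("linear" = interpolation between order
        statistics, the common spreadsheet default).
    min_group_size
        Use-group/endpoint combinations with fewer present values than
        this yield no criterion-1 flags.
    dt50_*_days, bcf_limit, noec_limit_mg_per_l
        PBT numeric thresholds (half-life per compartment in days,
        bioconcentration factor in L/kg, chronic NOEC in mg/L).
    t_human_classes
        CMR classes qualifying for the human-toxicity indicator of
        criterion 2 (STOT RE 1/2 always qualifies).
    pb_only_basis
        Hazard basis assigned to a substance that is CFS solely via
        P+B with no toxicity indicator ("human" or "environmental").
    preassessed_precedence
        Whether pre-assessed booleans override raw endpoint values.
    """

    percentile_q: float = 0.05
    quantile_method: str = "linear"
    min_group_size: int = 5
    dt50_water_days: float = 60.0
    dt50_sediment_days: float = 180.0
    dt50_soil_days: float = 120.0
    bcf_limit: float = 2000.0
    noec_limit_mg_per_l: float = 0.01
    t_human_classes: frozenset = frozenset({"1A", "1B", "2"})
    pb_only_basis: str = "human"
    preassessed_precedence: bool = True

    def __post_init__(self):
        if not 0.0 < self.percentile_q < 1.0:
            raise ConfigError(f"percentile_q must be in (0, 1), got {self.percentile_q}")
        for name in ("dt50_water_days", "dt50_sediment_days", "dt50_soil_days",
                     "bcf_limit", "noec_limit_mg_per_l"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.min_group_size < 1:
            raise ConfigError("min_group_size must be >= 1")
        if self.pb_only_basis not in ("human", "environmental"):
            raise ConfigError(
                f"pb_only_basis must be 'human' or 'environmental', "
                f"got {self.pb_only_basis!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassifierConfig":
        d = dict(d)
        if "t_human_classes" in d:
            d["t_human_classes"] = frozenset(str(x) for x in d["t_human_classes"])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "percentile_q": self.percentile_q,
            "quantile_method": self.quantile_method,
            "min_group_size": self.min_group_size,
            "dt50_water_days": self.dt50_water_days,
            "dt50_sediment_days": self.dt50_sediment_days,
            "dt50_soil_days": self.dt50_soil_days,
            "bcf_limit": self.bcf_limit,
            "noec_limit_mg_per_l": self.noec_limit_mg_per_l,
            "t_human_classes": sorted(self.t_human_classes),
            "pb_only_basis": self.pb_only_basis,
            "preassessed_precedence": self.preassessed_precedence,
        }


@dataclass(frozen=True)
class CFSAssessment:
    """Per-substance outcome: criterion flags, PBT sub-flags, CFS status."""

    substance_id: str
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    c6: bool
    c7: bool
    p: bool
    b: bool
    t_aqua: bool
    t_human: bool
    env_route: bool
    human_route: bool
    is_cfs: bool
    basis: str

    def __post_init__(self):
        if self.basis not in BASES:
            raise ConfigError(f"invalid basis {self.basis!r}")


def _pre(profile: HazardProfile, key: str, cfg: ClassifierConfig) -> Optional[bool]:
    if cfg.preassessed_precedence and key in profile.preassessed:
        return bool(profile.preassessed[key])
    return None


def eval_P(profile: HazardProfile, cfg: ClassifierConfig) -> bool:
    """Persistent: any present half-life strictly above its compartment
    threshold; merged across water, sediment and soil."""
    pre = _pre(profile, "P", cfg)
    if pre is not None:
        return pre
    checks = ((profile.dt50_water, cfg.dt50_water_days),
              (profile.dt50_sediment, cfg.dt50_sediment_days),
              (profile.dt50_soil, cfg.dt50_soil_days))
    return any(v is not None and v > thr for v, thr in checks)


def eval_B(profile: HazardProfile, cfg: ClassifierConfig) -> bool:
    """Bioaccumulative: BCF strictly above the limit."""
    pre = _pre(profile, "B", cfg)
    if pre is not None:
        return pre
    return profile.bcf is not None and profile.bcf > cfg.bcf_limit


def eval_T_aqua(profile: HazardProfile, cfg: ClassifierConfig) -> bool:
    """Aquatic toxicity: minimum present chronic NOEC across fish,
    daphnids, algae and other taxa strictly below the limit."""
    pre = _pre(profile, "T_aqua", cfg)
    if pre is not None:
        return pre
    noecs = [v for v in (profile.noec_fish, profile.noec_daphnia,
                         profile.noec_algae, profile.noec_other)
             if v is not None]
    return bool(noecs) and min(noecs) < cfg.noec_limit_mg_per_l


def eval_T_human(profile: HazardProfile, cfg: ClassifierConfig) -> bool:
    """Human toxicity indicator: any CMR classification in the
    qualifying class set, or STOT RE category 1 or 2."""
    pre = _pre(profile, "T_human", cfg)
    if pre is not None:
        return pre
    cmr = (profile.carc_class, profile.muta_class,
           profile.repro_class_existing, profile.repro_class_forthcoming)
    return (any(c in cfg.t_human_classes for c in cmr)
            or profile.stot_re_class in ("1", "2"))


def eval_criterion2(p: bool, b: bool, t_aqua: bool,
                    t_human: bool) -> Tuple[bool, bool, bool]:
    """Two-of-three PBT rule.

    Returns ``(met, env_route, human_route)``: the criterion is met
    when at least two of {P, B, T} hold with T = T_aqua or T_human;
    the environmental route pairs aquatic toxicity with P or B, the
    human route pairs the CMR/STOT indicator with P or B.  P+B with
    no toxicity indicator is met with both routes false.
    """
    t = t_aqua or t_human
    met = (int(p) + int(b) + int(t)) >= 2
    env_route = t_aqua and (p or b)
    human_route = t_human and (p or b)
    return met, env_route, human_route


def _severe_repro(profile: HazardProfile) -> str:
    """Merged reproductive-toxicity class: the more severe of the
    existing and forthcoming classifications."""
    return max(profile.repro_class_existing, profile.repro_class_forthcoming,
               key=_CMR_SEVERITY.__getitem__)


def eval_criterion4(profile: HazardProfile) -> bool:
    """Significant proportion of non-active isomers (abstracted flag)."""
    if profile.nonactive_isomer_flag is not None:
        return profile.nonactive_isomer_flag
    if "c4" in profile.preassessed:
        return bool(profile.preassessed["c4"])
    return False


def eval_criterion6(profile: HazardProfile) -> bool:
    """Toxic for reproduction category 1A or 1B, merging existing and
    forthcoming classifications."""
    return (profile.repro_class_existing in ("1A", "1B")
            or profile.repro_class_forthcoming in ("1A", "1B"))


def eval_criterion7(profile: HazardProfile) -> bool:
    """Interim endocrine-disruption rule: carcinogen category 2 together
    with (merged) reproductive toxicity category 2."""
    return profile.carc_class == "2" and _severe_repro(profile) == "2"


def eval_criterion1(profiles: Iterable[HazardProfile],
                    substances: Iterable[SubstanceRecord],
                    cfg: ClassifierConfig) -> Dict[str, bool]:
    """Flag substances whose ADI, ARfD or AOEL is strictly below the
    group q-quantile for any endpoint in any of their use groups.

    Substances in several use categories participate in the
    distribution of each; substances with no category participate in
    none and cannot be flagged.  Groups with fewer present values than
    ``cfg.min_group_size`` yield no flags.  Pre-assessed ``c1``
    booleans (when precedence is enabled) override the group
    computation for that substance.
    """
    substances = list(substances)
    profiles = list(profiles)
    if not substances:
        raise CaseloadError("criterion 1 requires a non-empty substance table")
    cats = {}
    for rec in substances:
        bad = set(rec.use_categories) - USE_CATEGORIES
        if bad:
            raise CaseloadError(
                f"substance {rec.substance_id!r}: unknown use category {sorted(bad)}")
        cats[rec.substance_id] = rec.use_categories

    flags = {prof.substance_id: False for prof in profiles}
    by_id = {prof.substance_id: prof for prof in profiles}

    for endpoint in ("adi", "arfd", "aoel"):
        groups: Dict[str, list] = {}
        for prof in profiles:
            v = getattr(prof, endpoint)
            if v is None:
                continue
            for cat in cats.get(prof.substance_id, frozenset()):
                groups.setdefault(cat, []).append((prof.substance_id, v))
        for cat, members in groups.items():
            if len(members) < cfg.min_group_size:
                continue
            values = np.array([v for _, v in members], dtype=float)
            q = float(np.quantile(values, cfg.percentile_q,
                                  method=cfg.quantile_method))
            for sid, v in members:
                if v < q:
                    flags[sid] = True

    for sid, prof in by_id.items():
        pre = _pre(prof, "c1", cfg)
        if pre is not None:
            flags[sid] = pre
    return flags


def hazard_basis(*, c1: bool, c2: bool, c4: bool, c6: bool, c7: bool,
                 env_route: bool, human_route: bool,
                 cfg: ClassifierConfig) -> str:
    """Assign the hazard basis of a CFS decision.

    Environmental identification: the aquatic-toxicity route of the
    PBT criterion, or non-active isomers.  Human identification: low
    reference doses (c1), reproductive toxicity 1A/1B (c6), the interim
    endocrine rule (c7), or the human-toxicity PBT route.  A substance
    CFS solely through P+B (no toxicity indicator) is attributed to the
    configured side.  Returns "none" when no criterion is met.
    """
    is_cfs = c1 or c2 or c4 or c6 or c7
    if not is_cfs:
        return "none"
    pb_only = c2 and not env_route and not human_route
    env = env_route or c4 or (pb_only and cfg.pb_only_basis == "environmental")
    human = (c1 or c6 or c7 or human_route
             or (pb_only and cfg.pb_only_basis == "human"))
    if env and human:
        return "both"
    return "env_only" if env else "human_only"


def classify_all(profiles: Iterable[HazardProfile],
                 substances: Iterable[SubstanceRecord],
                 cfg: Optional[ClassifierConfig] = None,
                 ) -> Dict[str, CFSAssessment]:
    """Evaluate all seven criteria for every substance.

    Pure function of (profiles, substances, config); the result maps
    substance_id to a :class:`CFSAssessment`.  Criteria 3 and 5 are
    constant false, keeping the disjunction structure of the legal
    list.
    """
    cfg = cfg or ClassifierConfig()
    profiles = list(profiles)
    substances = list(substances)
    prof_ids = {p.substance_id for p in profiles}
    rec_ids = {r.substance_id for r in substances}
    if len(prof_ids) != len(profiles):
        raise CaseloadError("duplicate substance_id among hazard profiles")
    if prof_ids != rec_ids:
        diff = prof_ids.symmetric_difference(rec_ids)
        raise CaseloadError(
            f"substance table and hazard table disagree on ids: {sorted(diff)[:5]}")

    c1_map = eval_criterion1(profiles, substances, cfg)

    out: Dict[str, CFSAssessment] = {}
    for prof in profiles:
        p = eval_P(prof, cfg)
        b = eval_B(prof, cfg)
        t_aqua = eval_T_aqua(prof, cfg)
        t_human = eval_T_human(prof, cfg)
        c2, env_route, human_route = eval_criterion2(p, b, t_aqua, t_human)
        c4 = eval_criterion4(prof)
        c6 = eval_criterion6(prof)
        c7 = eval_criterion7(prof)
        pre6 = _pre(prof, "c6", cfg)
        if pre6 is not None:
            c6 = pre6
        pre7 = _pre(prof, "c7", cfg)
        if pre7 is not None:
            c7 = pre7
        c1 = c1_map[prof.substance_id]
        is_cfs = c1 or c2 or c4 or c6 or c7
        basis = hazard_basis(c1=c1, c2=c2, c4=c4, c6=c6, c7=c7,
                             env_route=env_route, human_route=human_route,
                             cfg=cfg)
        out[prof.substance_id] = CFSAssessment(
            substance_id=prof.substance_id,
            c1=c1, c2=c2, c3=False, c4=c4, c5=False, c6=c6, c7=c7,
            p=p, b=b, t_aqua=t_aqua, t_human=t_human,
            env_route=env_route, human_route=human_route,
            is_cfs=is_cfs, basis=basis,
        )
    return out
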