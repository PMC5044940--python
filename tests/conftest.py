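import dataclasses

import pytest
from hypothesis import settings

import cfs_caseload as cc

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=60)
settings.load_profile("suite")


HAZARD_HEADER = ",".join(cc.registry.HAZARD_COLUMNS)


def make_hazard_csv(tmp_path, rows, name="hazard.csv"):
    """Write a hazard-table CSV from dicts of column -> cell text."""
    path = tmp_path / name
    lines = [HAZARD_HEADER]
    for row in rows:
        lines.append(",".join(str(row.get(c, "")) for c in cc.registry.HAZARD_COLUMNS))
    path.write_text("\n".join(lines) + "\n")
    return path


def make_registry_csvs(tmp_path, product_rows, use_rows,
                       pname="products.csv", uname="uses.csv"):
    ppath = tmp_path / pname
    upath = tmp_path / uname
    plines = ["product_id,name,substance_ids,categories"]
    plines += [",".join(r) for r in product_rows]
    ppath.write_text("\n".join(plines) + "\n")
    ulines = ["product_id,crop,pest"]
    ulines += [",".join(r) for r in use_rows]
    upath.write_text("\n".join(ulines) + "\n")
    return ppath, upath


def profile(sid="s1", **kw):
    return cc.HazardProfile(substance_id=sid, **kw)


@pytest.fixture(scope="session")
def preset_runs():
    """Full pipeline on the german-like preset over 20 seeds.

    Session-scoped because generation dominates the suite's runtime;
    every consumer treats the results as read-only.
    """
    runs = []
    for seed in range(20):
        cfg = cc.german_like_preset(seed)
        substances, profiles, reg = cc.generate_scenario(cfg)
        assessments = cc.classify_all(profiles, substances)
        report = cc.compute_workload(reg, assessments, "any")
        runs.append({
            "cfg": cfg,
            "substances": substances,
            "profiles": profiles,
            "registry": reg,
            "assessments": assessments,
            "report": report,
        })
    return runs


@pytest.fixture()
def toy_candidate_registry():
    """One candidate product with 2 uses; u1 has 3 alternatives, u2 none.

    Substance S-CFS is a CFS; A1..A3 contain only the CFS-free S-OK.
    """
    u1 = cc.normalize_use("apple", "aphids")
    u2 = cc.normalize_use("pear", "mites")
    products = {
        "C1": cc.Product("C1", "candidate", frozenset({"S-CFS"}), frozenset({"IN"})),
        "A1": cc.Product("A1", "alt 1", frozenset({"S-OK"}), frozenset({"IN"})),
        "A2": cc.Product("A2", "alt 2", frozenset({"S-OK"}), frozenset({"IN"})),
        "A3": cc.Product("A3", "alt 3", frozenset({"S-OK"}), frozenset({"IN"})),
    }
    auth = {
        "C1": frozenset({u1, u2}),
        "A1": frozenset({u1}),
        "A2": frozenset({u1}),
        "A3": frozenset({u1}),
    }
    reg = cc.Registry(products=products, authorisations=auth)
    cfg = cc.ClassifierConfig()
    assessments = {
        "S-CFS": _assess("S-CFS", c6=True, cfg=cfg),
        "S-OK": _assess("S-OK", cfg=cfg),
    }
    return reg, assessments, u1, u2


def _assess(sid, *, c1=False, c2=False, c4=False, c6=False, c7=False,
            p=False, b=False, t_aqua=False, t_human=False, cfg=None):
    cfg = cfg or cc.ClassifierConfig()
    _, env_route, human_route = cc.eval_criterion2(p, b, t_aqua, t_human)
    is_cfs = c1 or c2 or c4 or c6 or c7
    basis = cc.hazard_basis(c1=c1, c2=c2, c4=c4, c6=c6, c7=c7,
                            env_route=env_route, human_route=human_route,
                            cfg=cfg)
    return cc.CFSAssessment(
        substance_id=sid, c1=c1, c2=c2, c3=False, c4=c4, c5=False,
        c6=c6, c7=c7, p=p, b=b, t_aqua=t_aqua, t_human=t_human,
        env_route=env_route, human_route=human_route,
        is_cfs=is_cfs, basis=basis)


@pytest.fixture()
def assess():
    return _assess
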