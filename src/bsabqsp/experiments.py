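"""Virtual-trial analyses on calibrated virtual populations.

* dose-response of the stratified biochemical response rate across the
  weekly dose-escalation grid (plus 76 mg Q2W);
* per-patient binding-ratio-vs-exposure curve shapes (increasing, bell,
  decreasing) with a rank-based feature scan for their determinants;
* maintenance-of-response under dose-frequency de-escalation (QW -> Q2W at
  cycle 7, optionally Q2W -> Q4W at cycle 13) among persistent responders;
* comparison of PR-or-better vs VGPR-or-better switching criteria;
* the iterative logistic-regression scan selecting the baseline sBCMA
  cutoff that best separates responders.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import regimens as rg
from . import response as resp
from . import synthetic, vpop as vp
from .kinetics import (PatientModel, average_drug_concentration,
                       effective_binding_ratio)
from .params import PatientParameters

DOSE_GRID_MG = (16.0, 28.0, 44.0, 76.0, 152.0)


# ---------------------------------------------------------------------------
# dose-response study
# ---------------------------------------------------------------------------

def dose_response_study(pool: vp.PlausiblePool, vpops: list[vp.VPop],
                        regimen_ids: tuple[str, ...] = (
                            "flat_16_qw", "flat_28_qw", "flat_44_qw",
                            "flat_76_qw", "flat_152_qw", "flat_76_q2w"),
                        with_priming: bool = True,
                        solver_opts: dict | None = None) -> pd.DataFrame:
    """Stratified BRR of the pooled VPop members under each regimen.

    Each listed flat regimen is simulated with the two-step priming
    prepended (matching the calibration regimen) unless ``with_priming`` is
    False.  Members of all VPops are pooled for the point estimates;
    binomial (Wilson) intervals are computed on pooled counts.
    """
    if not regimen_ids:
        return pd.DataFrame(
            columns=["regimen", "stratum", "brr", "ci_low", "ci_high", "n"])
    member_pos = np.unique(np.concatenate([v.member_pos for v in vpops]))
    counts = np.bincount(
        np.concatenate([v.member_pos for v in vpops]), minlength=len(pool))

    rows = []
    for rid in regimen_ids:
        cache = _regimen_cache(pool, rid, with_priming, solver_opts)
        weights = counts[member_pos].astype(float)
        responder = cache.responder[member_pos]
        high = cache.high_sbcma[member_pos]
        for stratum, mask in (("low", ~high), ("high", high),
                              ("all", np.ones_like(high, dtype=bool))):
            n = int(weights[mask].sum())
            k = int(weights[mask][responder[mask]].sum())
            if n == 0:
                continue
            from statsmodels.stats.proportion import proportion_confint
            lo, hi = proportion_confint(k, n, method="wilson")
            rows.append((rid, stratum, k / n, float(lo), float(hi), n))
    return pd.DataFrame(rows, columns=["regimen", "stratum", "brr",
                                       "ci_low", "ci_high", "n"])


def _regimen_cache(pool: vp.PlausiblePool, rid: str, with_priming: bool,
                   solver_opts) -> vp.RegimenCache:
    """Reuse the pool cache when present, otherwise simulate and memoise."""
    key = f"{rid}+priming" if with_priming and rid.startswith("flat") else rid
    if key in pool.caches:
        return pool.caches[key]
    if with_priming and rid.startswith("flat"):
        base = rg.preset_regimen(rid)
        regimen = rg.primed(base.maintenance_dose, base.interval)
        cache = vp.simulate_cohort(pool.candidates, regimen_id=rid,
                                   base_params=pool.base_params,
                                   solver_opts=solver_opts,
                                   regimen=regimen)
    else:
        cache = vp.simulate_cohort(pool.candidates, rid,
                                   base_params=pool.base_params,
                                   solver_opts=solver_opts)
    pool.caches[key] = cache
    return cache


# ---------------------------------------------------------------------------
# binding-ratio curve shapes
# ---------------------------------------------------------------------------

def classify_curve_shape(ratios, tolerance: float = 0.02) -> tuple[str, bool]:
    """Label a binding-ratio sequence over increasing doses.

    Returns ``(label, quality_ok)``.  Non-decreasing (within relative
    ``tolerance``) is "increasing"; non-increasing is "decreasing"; a unique
    strict interior maximum is "bell".  A multi-peaked sequence is labelled
    "bell" with ``quality_ok=False``.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 doses to classify a curve shape")
    scale = np.max(np.abs(r))
    tol = tolerance * scale if scale > 0 else 0.0
    d = np.diff(r)
    if np.all(d >= -tol):
        return "increasing", True
    if np.all(d <= tol):
        return "decreasing", True
    peak = int(np.argmax(r))
    if 0 < peak < r.size - 1:
        rising = np.all(d[:peak] >= -tol)
        falling = np.all(d[peak:] <= tol)
        return "bell", bool(rising and falling)
    return "bell", False


def curve_shape_study(pool: vp.PlausiblePool, vpops: list[vp.VPop],
                      doses_mg: tuple[float, ...] = DOSE_GRID_MG,
                      window: tuple[float, float] = (0.0, 84.0),
                      tolerance: float = 0.02,
                      solver_opts: dict | None = None) -> pd.DataFrame:
    """Average exposure and binding ratio per dose for every VPop member.

    Each member is simulated at every weekly dose (two-step priming
    prepended); the average free central drug concentration and average
    effective binding ratio over the first three cycles are recorded and
    the concentration-response curve labelled.
    """
    member_pos = np.unique(np.concatenate([v.member_pos for v in vpops]))
    rows = []
    for i in member_pos:
        row = pool.candidates.iloc[int(i)]
        params, init = vp.build_patient(row, pool.base_params)
        model = PatientModel(params, init, solver_opts)
        concs, ratios = [], []
        for dose in doses_mg:
            res = model.simulate(rg.primed(dose), horizon=window[1],
                                 check_conservation=False)
            concs.append(average_drug_concentration(res, window))
            ratios.append(effective_binding_ratio(res, window))
        label, ok = classify_curve_shape(ratios, tolerance)
        rec = {"member_pos": int(i), "shape": label, "quality_ok": ok,
               "sbcma0": row["sbcma0"], "high_sbcma": bool(row["high_sbcma"])}
        for d, c, r in zip(doses_mg, concs, ratios):
            rec[f"conc_{d:g}"] = c
            rec[f"ratio_{d:g}"] = r
        rows.append(rec)
    return pd.DataFrame(rows).set_index("member_pos")


def feature_scan(features: pd.DataFrame, shapes: pd.Series,
                 joint_pair: tuple[str, str] | None = None) -> pd.DataFrame:
    """Kruskal-Wallis scan of each feature against curve-shape groups.

    ``features`` holds one column per candidate feature (parameters and
    initial states); ``shapes`` the per-patient labels.  A constant feature
    reports p = 1.  When ``joint_pair`` is given, a multinomial-logit
    likelihood-ratio test of the pair (vs intercept-only) is appended as row
    ``"joint:<a>+<b>"``.  Returns the table ranked by p-value with
    Benjamini-Hochberg adjusted p-values alongside the raw ones.
    """
    groups = shapes.unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 nonempty shape groups")
    rows = []
    for name in features.columns:
        samples = [features.loc[shapes == grp, name].to_numpy()
                   for grp in groups]
        if np.allclose(features[name].to_numpy(),
                       features[name].iloc[0]):
            rows.append((name, 0.0, 1.0))
            continue
        stat, p = sps.kruskal(*samples)
        rows.append((name, float(stat), float(p)))
    table = pd.DataFrame(rows, columns=["feature", "statistic", "p_value"])
    from statsmodels.stats.multitest import multipletests
    table["p_adj_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values("p_value").reset_index(drop=True)

    if joint_pair is not None:
        import statsmodels.api as sm
        a, b = joint_pair
        codes = pd.Categorical(shapes).codes
        X = sm.add_constant(
            (features[[a, b]] - features[[a, b]].mean())
            / features[[a, b]].std(ddof=0))
        full = sm.MNLogit(codes, np.asarray(X)).fit(disp=0, maxiter=200)
        null = sm.MNLogit(codes, np.ones((len(codes), 1))).fit(disp=0)
        lr = 2.0 * (full.llf - null.llf)
        dof = full.df_model
        if not np.isfinite(lr):   # separation / non-convergence
            lr, p = np.nan, np.nan
        else:
            p = float(sps.chi2.sf(lr, dof)) if dof > 0 else 1.0
        table = pd.concat([table, pd.DataFrame(
            [{"feature": f"joint:{a}+{b}", "statistic": float(lr),
              "p_value": p, "p_adj_bh": np.nan}])], ignore_index=True)
    return table


# ---------------------------------------------------------------------------
# switch scenarios
# ---------------------------------------------------------------------------

@dataclass
class SwitchStudyResult:
    """Paired per-patient outcomes under the de-escalation scenarios."""

    per_patient: pd.DataFrame       # one row per persistent responder
    pd_fraction: dict               # scenario -> fraction with PD by horizon
    shrinkage_gain: dict            # comparison -> fraction with deeper response
    trimer_ratio_tests: dict        # cycle -> (statistic, p) Wilcoxon paired
    n_responders: int


_SCENARIOS = {
    "constant_qw": None,
    "switch_q2w": rg.SwitchRule(),
    "switch_q2w_q4w": rg.SwitchRule(second_switch_cycle=13),
}


def switch_study(pool: vp.PlausiblePool, vpops: list[vp.VPop],
                 horizon: float = 1095.0,
                 depth: str = "PR",
                 solver_opts: dict | None = None) -> SwitchStudyResult:
    """Three de-escalation scenarios among persistent responders.

    Persistent responders to 76 mg QW (two-step priming) are re-simulated
    under (1) constant QW, (2) QW -> Q2W from cycle 7 after confirmation,
    (3) additionally Q2W -> Q4W from cycle 13.  Scenario trajectories are
    identical up to the first switch because the pre-switch inputs are
    identical.  Reported: PD fraction per scenario to ``horizon``, the
    fraction with greater tumor shrinkage under de-escalation at cycle 13
    and at end of therapy, and paired Wilcoxon tests on the trimer:tumor
    ratio at cycles 18 and 36.
    """
    cache = pool.cache("two_step_priming_76qw")
    member_pos = np.unique(np.concatenate([v.member_pos for v in vpops]))
    responders = member_pos[cache.persistent[member_pos]]
    if responders.size == 0:
        return SwitchStudyResult(pd.DataFrame(), {}, {}, {}, 0)

    regimen = rg.two_step_priming()
    scenarios = dict(_SCENARIOS)
    if depth == "VGPR":
        scenarios = {
            "constant_qw": None,
            "switch_q2w": rg.SwitchRule(depth="VGPR"),
            "switch_q2w_q4w": rg.SwitchRule(depth="VGPR",
                                            second_switch_cycle=13),
        }

    probe_days = {"c13": 13 * 28.0, "c18": 18 * 28.0, "c36": 36 * 28.0}
    rows = []
    for i in responders:
        row = pool.candidates.iloc[int(i)]
        params, init = vp.build_patient(row, pool.base_params)
        rec = {"member_pos": int(i)}
        for name, rule in scenarios.items():
            res, log = rg.simulate_adaptive(
                params, init, regimen.with_switch_rule(rule), horizon,
                solver_opts=solver_opts)
            track = resp.track_from_simulation(
                res, rg.assessment_days(regimen, horizon))
            pd_day = resp.detect_pd(track)
            rec[f"{name}_pd_day"] = pd_day if pd_day is not None else np.nan
            rec[f"{name}_switch_day"] = log[0][0] if log else np.nan
            for label, day in probe_days.items():
                day = min(day, horizon)
                rec[f"{name}_tumor_{label}"] = float(
                    np.interp(day, res.t, res.tumor_cells))
                rec[f"{name}_t2t_{label}"] = float(
                    np.interp(day, res.t, res.trimer_per_tumor_cell))
            rec[f"{name}_tumor_end"] = float(res.tumor_cells[-1])
        rows.append(rec)
    per_patient = pd.DataFrame(rows).set_index("member_pos")

    pd_fraction = {name: float(np.isfinite(per_patient[f"{name}_pd_day"]).mean())
                   for name in scenarios}
    shrinkage_gain = {
        "q2w_vs_qw_c13": float((per_patient["switch_q2w_tumor_c13"]
                                < per_patient["constant_qw_tumor_c13"]).mean()),
        "q4w_vs_q2w_end": float((per_patient["switch_q2w_q4w_tumor_end"]
                                 < per_patient["switch_q2w_tumor_end"]).mean()),
    }
    trimer_tests = {}
    for label in ("c18", "c36"):
        a = per_patient[f"switch_q2w_t2t_{label}"]
        b = per_patient[f"constant_qw_t2t_{label}"]
        if np.allclose(a, b):
            trimer_tests[label] = (0.0, 1.0)
        else:
            w = sps.wilcoxon(a, b, alternative="two-sided")
            trimer_tests[label] = (float(w.statistic), float(w.pvalue))
    return SwitchStudyResult(per_patient=per_patient,
                             pd_fraction=pd_fraction,
                             shrinkage_gain=shrinkage_gain,
                             trimer_ratio_tests=trimer_tests,
                             n_responders=int(responders.size))


def switch_criterion_study(pool: vp.PlausiblePool, vpops: list[vp.VPop],
                           horizon: float = 1095.0,
                           solver_opts: dict | None = None) -> dict:
    """PR-or-better vs VGPR-or-better switching criteria, paired."""
    out = {}
    for depth in ("PR", "VGPR"):
        res = switch_study(pool, vpops, horizon=horizon, depth=depth,
                           solver_opts=solver_opts)
        out[depth] = res
    pr = out["PR"]
    vg = out["VGPR"]
    summary = {
        "pd_fraction_PR": pr.pd_fraction.get("switch_q2w", np.nan),
        "pd_fraction_VGPR": vg.pd_fraction.get("switch_q2w", np.nan),
        "n_responders": pr.n_responders,
    }
    if len(pr.per_patient) and len(vg.per_patient):
        a = pr.per_patient["switch_q2w_t2t_c18"]
        b = vg.per_patient["switch_q2w_t2t_c18"]
        if np.allclose(a, b):
            summary["t2t_c18_test"] = (0.0, 1.0)
        else:
            w = sps.wilcoxon(a, b)
            summary["t2t_c18_test"] = (float(w.statistic), float(w.pvalue))
    return {"summary": summary, "PR": pr, "VGPR": vg}


# ---------------------------------------------------------------------------
# sBCMA threshold scan
# ---------------------------------------------------------------------------

def threshold_scan(data: pd.DataFrame, candidate_cutoffs) -> dict:
    """Iterative logistic-regression selection of the sBCMA cutoff.

    For each candidate cutoff a logistic model
    ``responder ~ 1(sBCMA >= cutoff)`` is fitted and the covariate p-value
    recorded; the cutoff with the smallest p-value wins.  Cutoffs leaving a
    stratum empty are skipped; complete separation falls back to a Firth-
    style penalised fit flag.  A flat profile (no association) is flagged
    low-confidence.
    """
    import statsmodels.api as sm
    cutoffs = np.asarray(sorted(candidate_cutoffs), dtype=float)
    if cutoffs.size < 2:
        raise ValueError("need >= 2 candidate cutoffs")
    s = data["sbcma0"].to_numpy()
    y = data["responder"].to_numpy().astype(int)
    rows = []
    for c in cutoffs:
        high = (s >= c).astype(float)
        if high.sum() == 0 or high.sum() == high.size:
            continue
        X = sm.add_constant(high)
        flagged = False
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            p = float(fit.pvalues[1])
            if not np.isfinite(p):
                raise ValueError("non-finite p")
        except Exception:
            # penalised fallback: score test on the 2x2 table
            flagged = True
            table = np.array([[np.sum((high == 0) & (y == 1)),
                               np.sum((high == 0) & (y == 0))],
                              [np.sum((high == 1) & (y == 1)),
                               np.sum((high == 1) & (y == 0))]])
            p = float(sps.chi2_contingency(table + 0.5)[1])
        rows.append((float(c), p, flagged))
    if not rows:
        raise ValueError("no candidate cutoff left both strata nonempty")
    profile = pd.DataFrame(rows, columns=["cutoff", "p_value", "penalised"])
    best = profile.loc[profile["p_value"].idxmin()]
    spread = profile["p_value"].max() - profile["p_value"].min()
    return {"selected_cutoff": float(best["cutoff"]),
            "p_value": float(best["p_value"]),
            "profile": profile,
            "low_confidence": bool(spread < 1e-3 or best["p_value"] > 0.05)}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str, outdir=None) -> dict:
    """Execute sample -> filter -> calibrate -> experiments from one config.

    ``config`` is a dict or a path to a YAML/JSON file.  Writes tidy CSV /
    JSON artifacts plus a run manifest into ``outdir`` (defaults to
    ``config["outdir"]``) and returns the in-memory results.  Deterministic
    given the seeds in the config.
    """
    import hashlib
    import json
    import platform
    from pathlib import Path

    if not isinstance(config, dict):
        import yaml
        with open(config) as fh:
            config = yaml.safe_load(fh)
    errors = _validate_config(config)
    if errors:
        raise ValueError("invalid pipeline config:\n- " + "\n- ".join(errors))

    outdir = Path(outdir if outdir is not None else config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    targets = synthetic.default_targets()
    if wanted := config.get("target_regimens"):
        targets = targets.subset(wanted)

    cand = vp.sample_trial_patients(int(config["pool_size"]), seed=seed)
    pool = vp.plausibility_filter(
        cand, bounds=tuple(config.get("doubling_bounds", vp.DOUBLING_BOUNDS)),
        regimen_ids=tuple(targets.regimen_ids))
    vpops = vp.calibrate_vpops(pool, targets,
                               k=int(config.get("n_vpops", 1)),
                               size=int(config.get("vpop_size", 120)),
                               seeds=[seed + i for i in
                                      range(int(config.get("n_vpops", 1)))],
                               ga_opts=config.get("ga_opts"))
    results: dict = {"pool": pool, "vpops": vpops}

    membership = pd.DataFrame(
        [{"vpop": k, "member": int(m)} for k, v in enumerate(vpops)
         for m in v.member_ids])
    membership.to_csv(outdir / "vpop_membership.csv", index=False)
    with open(outdir / "objectives.json", "w") as fh:
        json.dump([{"seed": v.seed, "objective": v.objective,
                    "breakdown": v.breakdown} for v in vpops], fh,
                  indent=1, default=float)
    vp.ks_bias_table(pool, vpops[0]).to_csv(outdir / "bias_check.csv")

    experiments = config.get("experiments", ["dose_response"])
    if "dose_response" in experiments:
        dr = dose_response_study(
            pool, vpops, regimen_ids=tuple(config.get(
                "dose_response_regimens",
                ("flat_16_qw", "flat_44_qw", "flat_76_qw"))))
        dr.to_csv(outdir / "dose_response.csv", index=False)
        results["dose_response"] = dr
    if "curve_shapes" in experiments:
        cs = curve_shape_study(pool, vpops)
        cs.to_csv(outdir / "curve_shapes.csv")
        results["curve_shapes"] = cs
    if "threshold_scan" in experiments:
        data = synthetic.generate_threshold_dataset(
            int(config.get("threshold_n", 500)), seed=seed)
        scan = threshold_scan(data, config.get(
            "threshold_cutoffs", np.arange(40, 201, 10)))
        scan["profile"].to_csv(outdir / "threshold_profile.csv", index=False)
        results["threshold_scan"] = scan
    if "switch_study" in experiments:
        sw = switch_study(pool, vpops,
                          horizon=float(config.get("switch_horizon", 1095.0)))
        sw.per_patient.to_csv(outdir / "switch_study.csv")
        results["switch_study"] = sw

    manifest = {
        "config": {k: v for k, v in config.items() if k != "outdir"},
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "python": platform.python_version(),
        "pool_plausible": len(pool),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return results


def _validate_config(config: dict) -> list[str]:
    errors = []
    if "seed" not in config:
        errors.append("missing 'seed'")
    if "pool_size" not in config:
        errors.append("missing 'pool_size'")
    elif int(config["pool_size"]) < 10:
        errors.append("'pool_size' must be >= 10")
    if "outdir" not in config:
        errors.append("missing 'outdir'")
    for key in ("n_vpops", "vpop_size", "threshold_n"):
        if key in config and int(config[key]) < 1:
            errors.append(f"'{key}' must be >= 1")
    known = rg.PRESETS.keys()
    for rid in config.get("target_regimens", []):
        if rid not in known:
            errors.append(f"unknown target regimen {rid!r}")
    return errors
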