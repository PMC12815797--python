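"""Preclinical tumor-growth analytics: caliper volume, tumor growth
inhibition (TGI), baseline-normalized AUC, HSA and Bliss-independence
synergy indices, 2x2 factorial ANOVA, and a block-randomization check.

Conventions:

* volumes come from the standard caliper formula V = L * W^2 / 2 (mm^3);
* TGI at day *d* defaults to the "delta" form
  ``100 * (1 - (T_d - T_0) / (C_d - C_0))`` on arm mean curves, with the
  simple ratio form ``100 * (1 - T_d / C_d)`` available;
* Bliss works on effect fractions f = TGI / 100 with negative fractions
  retained (an arm that grows faster than control has f < 0):
  expected = fA + fB - fA*fB, exceedance = f_combo - expected;
* HSA excess is the extra endpoint volume reduction of the combination
  beyond the best single agent, in mm^3;
* normalized AUC is the per-animal trapezoidal AUC of V(t)/V(0),
  averaged within an arm and expressed as a ratio to the control arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf


def tumor_volume(length: float, width: float) -> float:
    """Caliper volume V = L * W^2 / 2; swaps L/W (with a warning) if W > L."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    if width > length:
        warnings.warn("width exceeded length; dimensions swapped", stacklevel=2)
        length, width = width, length
    return length * width**2 / 2.0


def arm_mean_curve(study: pd.DataFrame, arm: str) -> pd.Series:
    """Mean volume per day for one arm (index = day)."""
    sub = study[study["arm"] == arm]
    if sub.empty:
        raise ValueError(f"arm {arm!r} not present in the study")
    return sub.groupby("day")["volume_mm3"].mean().sort_index()


def tgi(
    arm_curve: pd.Series,
    control_curve: pd.Series,
    day: float,
    method: str = "delta",
) -> float:
    """Percent tumor growth inhibition of an arm vs control at a day."""
    for curve, name in ((arm_curve, "arm"), (control_curve, "control")):
        for d in (0, day):
            if d not in curve.index:
                raise ValueError(f"{name} curve lacks day {d}")
    t0, td = arm_curve[0], arm_curve[day]
    c0, cd = control_curve[0], control_curve[day]
    if method == "delta":
        growth_c = cd - c0
        if growth_c <= 0:
            raise ValueError(
                "control arm did not grow; delta TGI undefined (use method='ratio')"
            )
        return 100.0 * (1.0 - (td - t0) / growth_c)
    if method == "ratio":
        return 100.0 * (1.0 - td / cd)
    raise ValueError(f"unknown TGI method {method!r}")


def delta_tgi(tgi_combo: float, tgi_monos: list[float]) -> float:
    """Improvement of the combination over the best monotherapy, in points."""
    if not tgi_monos:
        raise ValueError("need at least one monotherapy TGI")
    return float(tgi_combo - max(tgi_monos))


def normalized_auc(
    study: pd.DataFrame, arm: str, interval: tuple[float, float] = (0, 14)
) -> float:
    """Arm mean of per-animal trapezoidal AUC of V(t)/V(0), as a ratio to control."""

    def arm_auc(name: str) -> float:
        sub = study[study["arm"] == name]
        if sub.empty:
            raise ValueError(f"arm {name!r} not present in the study")
        aucs = []
        for _, traj in sub.groupby("animal"):
            traj = traj.sort_values("day")
            days = traj["day"].to_numpy(dtype=float)
            if 0 not in days:
                raise ValueError(f"animal in arm {name!r} lacks a day-0 measurement")
            in_win = (days >= interval[0]) & (days <= interval[1])
            v0 = float(traj.loc[traj["day"] == 0, "volume_mm3"].iloc[0])
            rel = traj["volume_mm3"].to_numpy(dtype=float)[in_win] / v0
            aucs.append(np.trapezoid(rel, days[in_win]))
        return float(np.mean(aucs))

    return arm_auc(arm) / arm_auc("control")


def synergy_indices(
    tgi_a: float,
    tgi_b: float,
    tgi_ab: float,
    mean_vol_a: float | None = None,
    mean_vol_b: float | None = None,
    mean_vol_ab: float | None = None,
) -> dict:
    """HSA and Bliss-independence synergy summaries from arm-level metrics.

    TGIs are percentages (negatives allowed and retained); mean volumes,
    if given, are endpoint arm means in mm^3 for the HSA excess.
    """
    fa, fb, fab = tgi_a / 100.0, tgi_b / 100.0, tgi_ab / 100.0
    bliss_expected = fa + fb - fa * fb
    bliss_exceedance = fab - bliss_expected
    hsa_excess = None
    if None not in (mean_vol_a, mean_vol_b, mean_vol_ab):
        hsa_excess = min(mean_vol_a, mean_vol_b) - mean_vol_ab
    return {
        "bliss_expected": float(bliss_expected),
        "bliss_exceedance": float(bliss_exceedance),
        "hsa_excess_mm3": None if hsa_excess is None else float(hsa_excess),
    }


def two_way_anova(
    endpoint_values, factor_a_on, factor_b_on
) -> pd.DataFrame:
    """2x2 factorial ANOVA (type-II SS); rows A, B, A:B, Residual."""
    y = np.asarray(endpoint_values, dtype=float)
    a = np.asarray(factor_a_on, dtype=int)
    b = np.asarray(factor_b_on, dtype=int)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("inputs must share one length")
    cells = {(ai, bi): int(((a == ai) & (b == bi)).sum()) for ai in (0, 1) for bi in (0, 1)}
    if any(n < 2 for n in cells.values()):
        raise ValueError(f"each 2x2 cell needs >= 2 observations, got {cells}")
    df = pd.DataFrame({"y": y, "A": a, "B": b})
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"}
    )
    return table


def randomization_check(baselines, arms) -> dict:
    """Per-arm and pooled baseline mean +/- SD; flags arms off by > 1 pooled SD."""
    baselines = np.asarray(baselines, dtype=float)
    arms = np.asarray(arms)
    if (baselines <= 0).any():
        raise ValueError("baseline volumes must be positive")
    pooled_mean = float(baselines.mean())
    pooled_sd = float(baselines.std(ddof=1)) if baselines.size > 1 else 0.0
    per_arm, flags = {}, []
    for arm in pd.unique(arms):
        v = baselines[arms == arm]
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        per_arm[str(arm)] = {"n": int(v.size), "mean": mean, "sd": sd}
        if pooled_sd > 0 and abs(mean - pooled_mean) > pooled_sd:
            flags.append(str(arm))
    return {
        "pooled": {"n": int(baselines.size), "mean": pooled_mean, "sd": pooled_sd},
        "per_arm": per_arm,
        "flagged_arms": flags,
    }


@dataclass
class SynergyReport:
    tgi_by_arm: dict
    tgi_method: str
    delta_tgi: float
    normalized_auc_by_arm: dict
    hsa_excess_mm3: float
    bliss_expected: float
    bliss_exceedance: float
    anova: pd.DataFrame
    randomization: dict
    endpoint_day: float

    def to_dict(self) -> dict:
        return {
            "endpoint_day": self.endpoint_day,
            "tgi_method": self.tgi_method,
            "tgi_percent": self.tgi_by_arm,
            "delta_tgi_points": self.delta_tgi,
            "normalized_auc": self.normalized_auc_by_arm,
            "hsa_excess_mm3": self.hsa_excess_mm3,
            "bliss_expected": self.bliss_expected,
            "bliss_exceedance": self.bliss_exceedance,
            "anova": {
                str(k): {"F": _maybe(v["F"]), "p": _maybe(v["PR(>F)"])}
                for k, v in self.anova.iterrows()
            },
            "randomization": self.randomization,
        }

    def summary(self) -> str:
        lines = [
            f"endpoint day {self.endpoint_day} (TGI method: {self.tgi_method})",
            *(f"  TGI {arm}: {v:+.1f}%" for arm, v in self.tgi_by_arm.items()),
            f"  dTGI combo - best mono: {self.delta_tgi:+.1f} points",
            *(
                f"  normalized AUC {arm}: {v:.3f}"
                for arm, v in self.normalized_auc_by_arm.items()
            ),
            f"  HSA excess: {self.hsa_excess_mm3:.1f} mm3",
            f"  Bliss expected {self.bliss_expected:.3f}, "
            f"exceedance {self.bliss_exceedance:.3f}",
        ]
        return "\n".join(lines)


def _maybe(x):
    return None if pd.isna(x) else float(x)


def analyze_study(
    study: pd.DataFrame,
    roles: dict[str, str],
    endpoint_day: float | None = None,
    tgi_method: str = "delta",
) -> SynergyReport:
    """Full efficacy report for a 4-arm study.

    ``roles`` maps role names (control, mono_a, mono_b, combo) to arm
    names in the study table.
    """
    for role in ("control", "mono_a", "mono_b", "combo"):
        if role not in roles:
            raise ValueError(f"roles must define {role!r}")
    curves = {role: arm_mean_curve(study, arm) for role, arm in roles.items()}
    if endpoint_day is None:
        common = set(curves["control"].index)
        for c in curves.values():
            common &= set(c.index)
        endpoint_day = max(common)

    tgis = {
        role: tgi(curves[role], curves["control"], endpoint_day, method=tgi_method)
        for role in ("mono_a", "mono_b", "combo")
    }
    tgis["control"] = 0.0
    dtgi = delta_tgi(tgis["combo"], [tgis["mono_a"], tgis["mono_b"]])
    aucs = {
        role: normalized_auc(study, arm, interval=(0, endpoint_day))
        for role, arm in roles.items()
    }
    syn = synergy_indices(
        tgis["mono_a"], tgis["mono_b"], tgis["combo"],
        mean_vol_a=curves["mono_a"][endpoint_day],
        mean_vol_b=curves["mono_b"][endpoint_day],
        mean_vol_ab=curves["combo"][endpoint_day],
    )

    end = study[study["day"] == endpoint_day]
    arm_to_role = {v: k for k, v in roles.items()}
    end = end[end["arm"].isin(arm_to_role)]
    role_of = end["arm"].map(arm_to_role)
    a_on = role_of.isin(["mono_a", "combo"]).astype(int)
    b_on = role_of.isin(["mono_b", "combo"]).astype(int)
    anova = two_way_anova(end["volume_mm3"], a_on, b_on)

    base = study[study["day"] == 0]
    rand = randomization_check(base["volume_mm3"], base["arm"])

    return SynergyReport(
        tgi_by_arm={r: float(tgis[r]) for r in ("control", "mono_a", "mono_b", "combo")},
        tgi_method=tgi_method,
        delta_tgi=float(dtgi),
        normalized_auc_by_arm={r: float(aucs[r]) for r in aucs},
        hsa_excess_mm3=syn["hsa_excess_mm3"],
        bliss_expected=syn["bliss_expected"],
        bliss_exceedance=syn["bliss_exceedance"],
        anova=anova,
        randomization=rand,
        endpoint_day=float(endpoint_day),
    )
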