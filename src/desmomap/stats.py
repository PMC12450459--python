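"""Group-comparison battery with explicit test-selection logic.

The selection procedure, applied to per-desmosome plaque-to-plaque values
(or any named groups of measurements), at preliminary-test α = 0.05:

* two groups: Shapiro–Wilk normality per group, then an unpaired two-tailed
  Student t-test;
* three or more groups: Shapiro–Wilk per group and Brown–Forsythe
  (median-centred Levene) equal-variance test; if variances are homogeneous,
  one-way ANOVA with Tukey's HSD post hoc; if not, Welch's ANOVA with
  Dunnett's T3 post hoc.

Every branch decision is recorded in an audit trail so the chosen procedure
is a pure, inspectable function of the preliminary outcomes.  The standard
tests are delegated to scipy/pingouin; the bespoke content here is the
selection logic, the audit trail, and the Dunnett T3 post hoc (pairwise
Welch t statistics referred to a studentized-maximum-modulus null,
approximated by the Šidák form ``1 − (2·F_t(t; ν) − 1)^k``).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = ["TestReport", "select_and_run", "dunnett_t3"]

_PRELIM_ALPHA_DOC = 0.05  # preliminary-test alpha; configurable but logged


@dataclass(frozen=True)
class TestReport:
    """Audit-trailed result of the group-comparison battery."""

    groups: dict                      # name -> n
    alpha: float
    shapiro_p: dict                   # name -> normality p-value
    variance_test: tuple | None       # (name, stat, p) or None for 2 groups
    omnibus: tuple                    # (name, stat, p)
    posthoc: pd.DataFrame | None      # group1, group2, stat, p_adj
    procedure: str                    # human-readable branch taken
    decisions: tuple                  # audit trail, one line per decision

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "alpha": self.alpha,
            "shapiro_p": self.shapiro_p,
            "variance_test": list(self.variance_test) if self.variance_test else None,
            "omnibus": list(self.omnibus),
            "posthoc": self.posthoc.to_dict(orient="records")
            if self.posthoc is not None
            else None,
            "procedure": self.procedure,
            "decisions": list(self.decisions),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        lines = [f"procedure: {self.procedure}"]
        for name, n in self.groups.items():
            lines.append(f"  {name}: n={n}, Shapiro-Wilk p={self.shapiro_p[name]:.4g}")
        if self.variance_test is not None:
            nm, st, p = self.variance_test
            lines.append(f"  {nm}: stat={st:.4g}, p={p:.4g}")
        nm, st, p = self.omnibus
        lines.append(f"  omnibus {nm}: stat={st:.4g}, p={p:.4g}")
        if self.posthoc is not None:
            for _, row in self.posthoc.iterrows():
                lines.append(
                    f"  {row['group1']} vs {row['group2']}: p_adj={row['p_adj']:.4g}"
                )
        lines.append("decision trail:")
        lines.extend(f"  - {d}" for d in self.decisions)
        return "\n".join(lines)


def _welch_df(v1, n1, v2, n2) -> float:
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den


def dunnett_t3(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunnett's T3 all-pairs comparison for unequal variances.

    Each pair gets a Welch t statistic with Satterthwaite degrees of
    freedom; the adjusted p-value refers it to the studentized maximum
    modulus with k = number of comparisons, approximated as
    ``1 − (2·F_t(|t|; ν) − 1)^k``.
    """
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    k = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        na, nb = len(xa), len(xb)
        se = math.sqrt(va / na + vb / nb)
        t = abs(xa.mean() - xb.mean()) / se if se > 0 else 0.0
        df = _welch_df(va, na, vb, nb) if se > 0 else na + nb - 2
        p = 1.0 - (2.0 * sps.t.cdf(t, df) - 1.0) ** k if t > 0 else 1.0
        rows.append(
            {"group1": a, "group2": b, "stat": t, "df": df, "p_adj": min(max(p, 0.0), 1.0)}
        )
    return pd.DataFrame(rows)


def _tukey(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    res = sps.tukey_hsd(*(np.asarray(groups[n], float) for n in names))
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group1": names[i],
                "group2": names[j],
                "stat": float(res.statistic[i, j]),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


def select_and_run(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TestReport:
    """Run the full selection procedure on named groups of values.

    Requires at least two groups with n ≥ 3 each.  Group order never
    affects any reported p-value.
    """
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if len(arr) < 3:
            raise DataError(f"group {name!r}: need n >= 3, got {len(arr)}")
        if not np.isfinite(arr).all():
            raise DataError(f"group {name!r}: non-numeric or non-finite values")
        clean[name] = arr

    decisions = []
    shapiro_p = {}
    for name, arr in clean.items():
        p = float(sps.shapiro(arr).pvalue)
        shapiro_p[name] = p
        verdict = "normal" if p > alpha else "non-normal"
        decisions.append(f"Shapiro-Wilk {name}: p={p:.4g} -> {verdict} at alpha={alpha}")

    if len(clean) == 2:
        (xa, xb) = clean.values()
        t, p = sps.ttest_ind(xa, xb, equal_var=True)
        decisions.append("2 groups -> unpaired two-tailed t-test")
        return TestReport(
            groups={k: len(v) for k, v in clean.items()},
            alpha=alpha,
            shapiro_p=shapiro_p,
            variance_test=None,
            omnibus=("t-test", float(t), float(p)),
            posthoc=None,
            procedure="Shapiro-Wilk; unpaired two-tailed t-test",
            decisions=tuple(decisions),
        )

    bf_stat, bf_p = sps.levene(*clean.values(), center="median")
    bf_p = float(bf_p)
    equal_var = bf_p > alpha
    decisions.append(
        f"Brown-Forsythe: p={bf_p:.4g} -> "
        f"{'equal' if equal_var else 'unequal'} variances at alpha={alpha}"
    )

    if equal_var:
        f, p = sps.f_oneway(*clean.values())
        posthoc = _tukey(clean)
        omnibus = ("one-way ANOVA", float(f), float(p))
        procedure = "Shapiro-Wilk; Brown-Forsythe; one-way ANOVA + Tukey HSD"
        decisions.append("equal variances -> one-way ANOVA with Tukey HSD post hoc")
    else:
        import pingouin as pg

        long = pd.DataFrame(
            [(name, v) for name, arr in clean.items() for v in arr],
            columns=["group", "value"],
        )
        aov = pg.welch_anova(data=long, dv="value", between="group")
        omnibus = ("Welch ANOVA", float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0]))
        posthoc = dunnett_t3(clean)
        procedure = "Shapiro-Wilk; Brown-Forsythe; Welch ANOVA + Dunnett T3"
        decisions.append("unequal variances -> Welch ANOVA with Dunnett T3 post hoc")

    return TestReport(
        groups={k: len(v) for k, v in clean.items()},
        alpha=alpha,
        shapiro_p=shapiro_p,
        variance_test=("Brown-Forsythe", float(bf_stat), bf_p),
        omnibus=omnibus,
        posthoc=posthoc.sort_values(["group1", "group2"]).reset_index(drop=True),
        procedure=procedure,
        decisions=tuple(decisions),
    )
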