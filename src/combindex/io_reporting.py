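"""Reading well-level CSVs, control normalization and study-level reports.

The long-format well table has one row per well:

    experiment_id, agent_a, dose_a, agent_b, dose_b, replicate,
    signal (or viability), is_control

Controls carry dose 0 on both agents.  A file declares exactly one of
``signal`` (raw optical density) or ``viability`` (already normalized
fraction) in its header.  Normalization divides every signal by the mean
control signal of the same experiment; fraction affected is 1 - viability,
clamped to [0, 1] with each clamp logged.

``run_study`` drives the whole pipeline — per-experiment single-agent
fits, IC50 aggregation, per-level CI with classification, pooled Fa-CI
curves — and writes CSV tables, plots and an exclusions log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import combination as comb
from .combination import (
    ConstantRatioDesign,
    aggregate,
    classify_ci,
    fa_ci_curve,
)
from .errors import CombindexError, DomainError, FitInfeasibleError, ModelInvalidError
from .median_effect import (
    DoseResponseDataset,
    MedianEffectModel,
    fit_median_effect,
)
from .synthetic import WELL_COLUMNS

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("experiment_id", "agent_a", "dose_a", "replicate",
                     "is_control")

__all__ = [
    "read_wells",
    "write_wells",
    "normalize",
    "run_study",
    "StudyReport",
    "MalformedRowsError",
]


class MalformedRowsError(CombindexError):
    """CSV rows failed validation; carries (line_number, reason) pairs."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"line {ln}: {why}" for ln, why in problems[:10])
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        super().__init__(f"malformed rows: {lines}{more}")


def read_wells(path) -> pd.DataFrame:
    """Read and validate a long-format well CSV.

    The header declares the value column: exactly one of ``signal`` or
    ``viability`` must be present.  Malformed rows (negative doses,
    controls with non-zero dose, values that do not parse) are collected
    into a :class:`MalformedRowsError` naming 1-based file line numbers.
    """
    df = pd.read_csv(path, dtype={"experiment_id": str, "agent_a": str,
                                  "agent_b": str}, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"missing mandatory columns: {missing}")
    has_signal = "signal" in df.columns
    has_viability = "viability" in df.columns
    if has_signal == has_viability:
        raise DomainError(
            "exactly one of 'signal' or 'viability' must be declared"
        )
    value_col = "signal" if has_signal else "viability"

    if "agent_b" not in df.columns:
        df["agent_b"] = ""
    if "dose_b" not in df.columns:
        df["dose_b"] = 0.0

    problems: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            da, db = float(row["dose_a"] or 0), float(row["dose_b"] or 0)
            val = float(row[value_col])
        except (TypeError, ValueError) as exc:
            problems.append((line, f"unparseable number: {exc}"))
            continue
        if da < 0 or db < 0:
            problems.append((line, f"negative dose ({da}, {db})"))
        is_ctrl = _as_bool(row["is_control"])
        if is_ctrl and (da != 0 or db != 0):
            problems.append((line, "control well with non-zero dose"))
        if not is_ctrl and da == 0 and db == 0:
            problems.append((line, "treated well with zero dose"))
        if not np.isfinite(val):
            problems.append((line, f"non-finite {value_col}"))
    if problems:
        raise MalformedRowsError(problems)

    df["dose_a"] = df["dose_a"].replace("", 0.0).astype(float)
    df["dose_b"] = df["dose_b"].replace("", 0.0).astype(float)
    df[value_col] = df[value_col].astype(float)
    df["is_control"] = df["is_control"].map(_as_bool)
    df["replicate"] = df["replicate"].astype(int)
    df.attrs["value_kind"] = value_col
    return df


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in {"true", "1", "yes", "t"}


def write_wells(df: pd.DataFrame, path) -> None:
    """Write a well table in the canonical column order."""
    cols = [c for c in WELL_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


@dataclass
class NormalizedStudy:
    """Per-arm, per-experiment dose-response datasets plus bookkeeping."""

    single_agent: dict[tuple[str, str], DoseResponseDataset]
    combination: dict[tuple[str, str, str], DoseResponseDataset]
    ratios: dict[tuple[str, str], float]  # (agent_a, agent_b) -> dose_a/dose_b
    clamp_log: list[dict] = field(default_factory=list)


def normalize(df: pd.DataFrame) -> NormalizedStudy:
    """Control-normalize well signals and group into datasets.

    Viability is signal over the mean control signal of the same
    experiment (skipped when the file already carries viability);
    fa = 1 - viability, clamped to [0, 1] with every clamp logged.
    Replicates are averaged to one fa per dose per experiment before
    fitting.  Single-agent arms key on (agent, experiment); combination
    arms on (agent_a, agent_b, experiment), with dose = total dose.
    """
    value_kind = df.attrs.get("value_kind", "signal")
    df = df.copy()
    if value_kind == "signal":
        ctrl_mean = (df[df["is_control"]]
                     .groupby("experiment_id")["signal"].mean())
        missing = set(df["experiment_id"]) - set(ctrl_mean.index)
        if missing:
            raise DomainError(
                f"experiments without control wells: {sorted(missing)}")
        df["viability"] = df["signal"] / df["experiment_id"].map(ctrl_mean)
    treated = df[~df["is_control"]].copy()

    clamp_log: list[dict] = []
    fa_raw = 1.0 - treated["viability"].to_numpy()
    fa = np.clip(fa_raw, 0.0, 1.0)
    for i in np.nonzero(fa != fa_raw)[0]:
        row = treated.iloc[i]
        clamp_log.append(dict(
            experiment_id=row["experiment_id"], agent_a=row["agent_a"],
            agent_b=row["agent_b"], dose_a=row["dose_a"],
            dose_b=row["dose_b"], fa_raw=float(fa_raw[i]),
            fa_clamped=float(fa[i]),
        ))
        logger.info("clamped fa=%g to %g (%s)", fa_raw[i], fa[i],
                    dict(row[["experiment_id", "agent_a", "dose_a"]]))
    treated["fa"] = fa

    single: dict[tuple[str, str], DoseResponseDataset] = {}
    combo: dict[tuple[str, str, str], DoseResponseDataset] = {}
    ratios: dict[tuple[str, str], float] = {}

    is_combo = treated["agent_b"].astype(str) != ""
    singles = treated[~is_combo]
    for (agent, exp), grp in singles.groupby(["agent_a", "experiment_id"]):
        means = grp.groupby("dose_a")["fa"].mean().sort_index()
        single[(agent, exp)] = DoseResponseDataset.from_arrays(
            agent, exp, means.index.to_numpy(), means.to_numpy())

    combos = treated[is_combo].copy()
    combos["total_dose"] = combos["dose_a"] + combos["dose_b"]
    for (a, b, exp), grp in combos.groupby(
            ["agent_a", "agent_b", "experiment_id"]):
        means = grp.groupby("total_dose")["fa"].mean().sort_index()
        combo[(a, b, exp)] = DoseResponseDataset.from_arrays(
            f"{a}+{b}", exp, means.index.to_numpy(), means.to_numpy())
        if (a, b) not in ratios:
            r = (grp["dose_a"] / grp["dose_b"]).to_numpy()
            if not np.allclose(r, r[0], rtol=1e-6):
                logger.warning(
                    "combination %s+%s is not on a constant ratio "
                    "(range %g-%g)", a, b, r.min(), r.max())
            ratios[(a, b)] = float(r[0])

    return NormalizedStudy(single_agent=single, combination=combo,
                           ratios=ratios, clamp_log=clamp_log)


@dataclass
class StudyReport:
    """Aggregated study-level results.

    ``ic50_table``: one row per agent with mean +/- SD IC50 over
    experiments.  ``ci_table``: one row per pair per design level with
    mean +/- SD CI and its verbal classification.  ``flags`` collects
    every exclusion, clamp and failed fit; nothing is silently dropped.
    """

    ic50_table: pd.DataFrame
    ci_table: pd.DataFrame
    profiles: dict[tuple[str, str], comb.FaCIProfile]
    flags: list[dict] = field(default_factory=list)


def run_study(
    wells: pd.DataFrame,
    out_dir=None,
    fa_eps: float = 0.01,
    fa_grid=comb.DEFAULT_FA_GRID,
    make_plots: bool = True,
) -> StudyReport:
    """Full pipeline: normalize, fit, compute CIs, report.

    Parameters
    ----------
    wells : DataFrame
        Long-format well records (as from :func:`read_wells` or the
        synthetic generator).
    out_dir : path-like, optional
        If given, writes ``ic50_table.csv``, ``ci_table.csv``,
        ``fa_ci_<pair>.csv`` (+ ``.png`` plots), ``report.txt``,
        ``ci_scale.csv`` and ``flags.json`` there.
    """
    if "value_kind" not in wells.attrs:
        wells = wells.copy()
        wells.attrs["value_kind"] = (
            "viability" if "viability" in wells.columns else "signal")
    norm = normalize(wells)
    flags: list[dict] = [dict(kind="fa-clamped", **c) for c in norm.clamp_log]

    # --- per-experiment single-agent fits -------------------------------
    fits: dict[tuple[str, str], MedianEffectModel] = {}
    agents = sorted({a for a, _ in norm.single_agent})
    experiments = sorted({e for _, e in norm.single_agent})
    for key, ds in norm.single_agent.items():
        try:
            model = fit_median_effect(ds, fa_eps=fa_eps)
        except (FitInfeasibleError, ModelInvalidError) as exc:
            flags.append(dict(kind="fit-failed", agent=key[0],
                              experiment=key[1], reason=str(exc)))
            continue
        fits[key] = model
        if model.excluded:
            flags.append(dict(
                kind="points-excluded", agent=key[0], experiment=key[1],
                n_excluded=len(model.excluded),
                points=[(o.dose, o.fa) for o in model.excluded]))
        if model.r < 0.90:
            flags.append(dict(kind="low-r", agent=key[0],
                              experiment=key[1], r=model.r))

    ic50_rows = []
    for agent in agents:
        dms = [fits[(agent, e)].dm for e in experiments
               if (agent, e) in fits]
        if not dms:
            flags.append(dict(kind="agent-unfittable", agent=agent))
            continue
        agg = aggregate(dms)
        ic50_rows.append(dict(agent=agent, ic50_mean=agg.mean,
                              ic50_sd=agg.sd, n=agg.n))
    ic50_table = pd.DataFrame(
        ic50_rows, columns=["agent", "ic50_mean", "ic50_sd", "n"])

    # --- combinations ----------------------------------------------------
    pairs = sorted({(a, b) for a, b, _ in norm.combination})
    multipliers = sorted({round(m, 12) for m in _infer_multipliers(norm)}) \
        if pairs else []
    ci_rows = []
    profiles: dict[tuple[str, str], comb.FaCIProfile] = {}
    for a, b in pairs:
        ratio = norm.ratios[(a, b)]  # administered dose_a / dose_b
        rho_a = ratio / (1.0 + ratio)
        # design anchored on the administered doses for reporting/profiles
        any_key = next(k for k in norm.combination if k[:2] == (a, b))
        totals = sorted({o.dose for o in
                         norm.combination[any_key].observations})
        anchor_total = totals[len(totals) // 2]  # the 1x level
        design = ConstantRatioDesign(
            agent_a=a, agent_b=b,
            ic50_a=rho_a * anchor_total, ic50_b=(1 - rho_a) * anchor_total)

        # per-level CI from administered doses, each experiment analyzed
        # with its own single-agent fits
        for mult in multipliers:
            per_level: list[float] = []
            for exp in experiments:
                key = (a, b, exp)
                if key not in norm.combination:
                    continue
                if (a, exp) not in fits or (b, exp) not in fits:
                    flags.append(dict(kind="experiment-excluded",
                                      pair=f"{a}+{b}", experiment=exp,
                                      reason="missing single-agent fit"))
                    continue
                fa_obs = _fa_at_level(norm.combination[key], mult)
                if fa_obs is None:
                    continue
                total = mult * anchor_total
                meas_doses = (rho_a * total, (1 - rho_a) * total)
                try:
                    res = comb.combination_index(
                        comb.CombinationMeasurement(
                            dose_a=meas_doses[0], dose_b=meas_doses[1],
                            fa_observed=fa_obs),
                        fits[(a, exp)], fits[(b, exp)])
                except (DomainError, comb.UndefinedCIError) as exc:
                    flags.append(dict(kind="ci-undefined", pair=f"{a}+{b}",
                                      experiment=exp, multiplier=mult,
                                      reason=str(exc)))
                    continue
                per_level.append(res.ci)
            if not per_level:
                continue
            agg = aggregate(per_level)
            label = classify_ci(agg.mean).label
            ci_rows.append(dict(
                agent_a=a, agent_b=b, multiplier=mult, ci_mean=agg.mean,
                ci_sd=agg.sd, n=agg.n, classification=label))

        # pooled mixture fit -> Fa-CI profile
        mix_models = []
        for exp in experiments:
            key = (a, b, exp)
            if key not in norm.combination:
                continue
            try:
                mix_models.append(
                    comb.fit_mixture(design, norm.combination[key],
                                     fa_eps=fa_eps))
            except (FitInfeasibleError, ModelInvalidError) as exc:
                flags.append(dict(kind="mixture-fit-failed", pair=f"{a}+{b}",
                                  experiment=exp, reason=str(exc)))
        if not mix_models:
            flags.append(dict(kind="profile-skipped", pair=f"{a}+{b}",
                              reason="no mixture fit"))
            continue
        pooled = MedianEffectModel(
            dm=float(10 ** np.mean([np.log10(m.dm) for m in mix_models])),
            m=float(np.mean([m.m for m in mix_models])),
            r=float(np.mean([m.r for m in mix_models])),
            n_fit=int(sum(m.n_fit for m in mix_models)))
        pooled_a = _pooled_model([fits[(a, e)] for e in experiments
                                  if (a, e) in fits])
        pooled_b = _pooled_model([fits[(b, e)] for e in experiments
                                  if (b, e) in fits])
        profiles[(a, b)] = fa_ci_curve(pooled_a, pooled_b, pooled,
                                       design, fa_grid)

    ci_table = pd.DataFrame(ci_rows, columns=[
        "agent_a", "agent_b", "multiplier", "ci_mean", "ci_sd", "n",
        "classification"])

    report = StudyReport(ic50_table=ic50_table, ci_table=ci_table,
                         profiles=profiles, flags=flags)
    if out_dir is not None:
        _write_artifacts(report, Path(out_dir), make_plots=make_plots)
    return report


def _pooled_model(models: list[MedianEffectModel]) -> MedianEffectModel:
    """Average per-experiment fits on the parameter scale (log dm, m)."""
    return MedianEffectModel(
        dm=float(10 ** np.mean([np.log10(m.dm) for m in models])),
        m=float(np.mean([m.m for m in models])),
        r=float(np.mean([m.r for m in models])),
        n_fit=int(sum(m.n_fit for m in models)))


def _infer_multipliers(norm: NormalizedStudy) -> list[float]:
    """Design levels of the combination arms as total-dose ratios.

    With the constant-ratio design anchored at the true IC50s, total dose
    at level k is multiplier_k x (ic50_a + ic50_b); ratios of the sorted
    total doses recover the multipliers up to the overall anchor scale,
    which we normalize so that the levels match the canonical series when
    they do and remain usable otherwise.
    """
    for (a, b, _exp), ds in norm.combination.items():
        totals = sorted({o.dose for o in ds.observations})
        # anchor on the level closest to the geometric mid of the series
        mid = totals[len(totals) // 2]
        return [t / mid for t in totals]
    return []


def _fa_at_level(ds: DoseResponseDataset, multiplier: float) -> float | None:
    """Observed mean fa of a combination dataset at one design level."""
    target = None
    totals = sorted({o.dose for o in ds.observations})
    mid = totals[len(totals) // 2]
    for ob in ds.observations:
        if np.isclose(ob.dose / mid, multiplier, rtol=1e-9):
            target = ob.fa
    return target


def _write_artifacts(report: StudyReport, out_dir: Path,
                     make_plots: bool = True) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = dict(index=False, float_format="%.6g")
    report.ic50_table.to_csv(out_dir / "ic50_table.csv", **fmt)
    report.ci_table.to_csv(out_dir / "ci_table.csv", **fmt)

    scale_rows = [dict(label=b.label, lower=b.lower, upper=b.upper,
                       lower_closed=b.lower_closed,
                       upper_closed=b.upper_closed)
                  for b in comb.CI_SCALE]
    pd.DataFrame(scale_rows).to_csv(out_dir / "ci_scale.csv", index=False)

    for (a, b), prof in report.profiles.items():
        stem = f"fa_ci_{a}_{b}"
        pd.DataFrame({"fa": prof.fa_grid, "ci": prof.ci_values}).to_csv(
            out_dir / f"{stem}.csv", index=False, float_format="%.8g")
        if make_plots:
            _plot_profile(prof, a, b, out_dir / f"{stem}.png")

    with open(out_dir / "flags.json", "w") as fh:
        json.dump(report.flags, fh, indent=1, default=str)

    with open(out_dir / "report.txt", "w") as fh:
        fh.write("Single-agent IC50 (mean +/- SD, n experiments)\n")
        for row in report.ic50_table.itertuples():
            sd = "undefined" if np.isnan(row.ic50_sd) else f"{row.ic50_sd:.3f}"
            fh.write(f"  {row.agent}: {row.ic50_mean:.3f} +/- {sd} "
                     f"(n={row.n})\n")
        fh.write("\nCombination index by design level "
                 "(mean +/- SD, n experiments)\n")
        for row in report.ci_table.itertuples():
            sd = "undefined" if np.isnan(row.ci_sd) else f"{row.ci_sd:.3f}"
            fh.write(f"  {row.agent_a}+{row.agent_b} @ {row.multiplier:g}x: "
                     f"CI = {row.ci_mean:.3f} +/- {sd} (n={row.n}) "
                     f"[{row.classification}]\n")
        if report.flags:
            fh.write(f"\n{len(report.flags)} flag(s); see flags.json\n")


def _plot_profile(prof: comb.FaCIProfile, a: str, b: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(prof.fa_grid, prof.ci_values, lw=1.5)
    ax.axhline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("fraction affected (fa)")
    ax.set_ylabel("combination index (CI)")
    ax.set_title(f"{a} + {b}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
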