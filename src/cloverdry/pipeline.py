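"""From raw daily pot weights to (FTSW, NTR) response points.

The chain, applied per experiment and per cultivar:

1. daily water loss per pot from consecutive weighings (irrigated pots are
   weighed before rewatering, so their loss is referenced to the full pot);
2. evaporation correction by subtracting the mean daily loss of bare pots,
   floored at zero, applied symmetrically to drought and control pots;
3. transpiration ratio TR: drought-pot corrected loss over the mean
   corrected loss of that cultivar's control pots on the same day;
4. normalized transpiration rate NTR: TR over its well-watered baseline,
   the mean TR of days 3 and 5;
5. fraction of transpirable soil water FTSW from raw weights, anchored at 1
   on the first day and 0 on the last.

TR is a ratio of daily water *losses* by default, the only reading under
which NTR sits near 1 while water is ample; a literal weight-ratio variant
(``tr_mode="weight_ratio"``) is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import WEIGHING_COLUMNS, WeighingDataset

__all__ = [
    "validate_weighing",
    "daily_water_loss",
    "correct_evaporation",
    "transpiration_ratio",
    "normalize_ntr",
    "fraction_tsw",
    "build_response_points",
    "ResponsePoints",
]

POINT_COLUMNS = ["cultivar", "replicate", "day", "ftsw", "ntr"]
LOG_COLUMNS = ["experiment_id", "cultivar", "replicate", "day", "reason"]


class PipelineError(ValueError):
    """Raised when an input series violates a pipeline precondition."""


def validate_weighing(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format weighing schema and basic sanity.

    Requires columns ``experiment_id,pot_id,cultivar,treatment,replicate,
    day,weight_g``, treatments restricted to drought/irrigated/bare,
    positive weights, and for every pot an unbroken 1..n day range.
    Returns the frame with canonical column order and dtypes.
    """
    missing = [c for c in WEIGHING_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineError(f"weighing table missing columns: {missing}")
    out = df[WEIGHING_COLUMNS].copy()
    out["day"] = out["day"].astype(int)
    out["weight_g"] = out["weight_g"].astype(float)
    bad = set(out["treatment"]) - {"drought", "irrigated", "bare"}
    if bad:
        raise PipelineError(f"unknown treatments: {sorted(bad)}")
    if (out["weight_g"] <= 0).any():
        raise PipelineError("non-positive pot weights present")
    for pot, grp in out.groupby("pot_id"):
        days = np.sort(grp["day"].to_numpy())
        if len(days) != len(set(days)):
            raise PipelineError(f"pot {pot}: duplicated days")
        if days[0] != 1 or not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise PipelineError(f"pot {pot}: days must run 1..n without gaps")
    return out


def _ordered_weights(days, weights_g) -> tuple[np.ndarray, np.ndarray]:
    days = np.asarray(days, dtype=int)
    w = np.asarray(weights_g, dtype=float)
    if len(days) != len(w):
        raise PipelineError("days and weights differ in length")
    if len(np.unique(days)) != len(days):
        raise PipelineError("duplicated days in series")
    if not np.all(np.diff(days) > 0):
        order = np.argsort(days)
        days, w = days[order], w[order]
    return days, w


def daily_water_loss(days, weights_g, rewatered: bool = False) -> pd.Series:
    """Daily water loss in grams, indexed by day 2..n.

    For a pot that simply dries, loss on day d is weight[d-1] - weight[d].
    For a pot rewatered to saturation after each weighing (``rewatered``),
    the previous evening's state was the initial saturated weight, so loss
    on day d is weight[1] - weight[d].
    """
    days, w = _ordered_weights(days, weights_g)
    if len(days) < 2:
        raise PipelineError("need at least two days to compute a loss")
    if rewatered:
        loss = w[0] - w[1:]
    else:
        loss = w[:-1] - w[1:]
    return pd.Series(loss, index=pd.Index(days[1:], name="day"), name="loss_g")


def correct_evaporation(loss: pd.Series, bare_mean_loss: pd.Series) -> pd.Series:
    """Subtract the mean bare-pot loss day by day, flooring at zero."""
    if (bare_mean_loss < 0).any():
        raise PipelineError("bare-pot mean loss must be non-negative")
    missing = loss.index.difference(bare_mean_loss.index)
    if len(missing):
        raise PipelineError(f"bare-pot series missing days {list(missing)}")
    corrected = (loss - bare_mean_loss.reindex(loss.index)).clip(lower=0.0)
    return corrected.rename("loss_corrected_g")


def transpiration_ratio(drought_loss: pd.Series, control_losses: list[pd.Series]) -> pd.Series:
    """TR per day: drought loss over the mean of the control losses.

    Days where the control mean is zero are returned as NaN; downstream
    steps exclude them with a logged reason rather than dividing by zero.
    """
    if not control_losses:
        raise PipelineError("at least one control series is required")
    controls = pd.concat(control_losses, axis=1)
    if controls.isna().any().any():
        raise PipelineError("control series do not cover the same days")
    mean_control = controls.mean(axis=1).reindex(drought_loss.index)
    if mean_control.isna().any():
        raise PipelineError("controls do not cover all drought-pot days")
    tr = drought_loss / mean_control.where(mean_control > 0)
    return tr.rename("tr")


def normalize_ntr(tr: pd.Series, baseline_days: tuple[int, ...] = (3, 5)) -> pd.Series:
    """NTR per day: TR over the mean TR of the well-watered baseline days.

    Days 3 and 5 are taken as well watered, so NTR is near 1 while soil
    water is ample.  Raises if a baseline day is absent or the baseline is
    not positive.
    """
    for d in baseline_days:
        if d not in tr.index or pd.isna(tr.loc[d]):
            raise PipelineError(f"baseline day {d} missing or undefined")
    baseline = float(np.mean([tr.loc[d] for d in baseline_days]))
    if baseline <= 0:
        raise PipelineError(f"non-positive TR baseline ({baseline}) on days {baseline_days}")
    return (tr / baseline).rename("ntr")


def fraction_tsw(days, weights_g) -> pd.Series:
    """FTSW per day from raw weights: (w[d] - w[last]) / (w[1] - w[last]).

    Clamped to [0, 1]; exactly 1 on the first day and 0 on the last.
    Raises for a degenerate pot whose initial weight does not exceed its
    final weight.
    """
    days, w = _ordered_weights(days, weights_g)
    if w[0] <= w[-1]:
        raise PipelineError("degenerate pot: initial weight must exceed final weight")
    ftsw = (w - w[-1]) / (w[0] - w[-1])
    return pd.Series(
        np.clip(ftsw, 0.0, 1.0), index=pd.Index(days, name="day"), name="ftsw"
    )


@dataclass
class ResponsePoints:
    """Assembled per-cultivar response points plus an exclusion log.

    ``points`` holds one row per drought pot per day with defined NTR and
    FTSW; ``log`` records every excluded day or skipped pot/cultivar with
    its reason.
    """

    points: pd.DataFrame
    log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=LOG_COLUMNS)
    )

    def for_cultivar(self, name: str) -> pd.DataFrame:
        return self.points[self.points["cultivar"] == name]


def build_response_points(
    data: WeighingDataset | pd.DataFrame,
    tr_mode: str = "loss_ratio",
    baseline_days: tuple[int, ...] = (3, 5),
    ftsw_pairing: str = "mid",
    exclude_exhaustion_day: bool = True,
) -> ResponsePoints:
    """Join NTR and FTSW by pot and day across all experiments.

    Bare pots of each experiment provide that experiment's evaporation
    series; control pots are all irrigated replicates of the same cultivar
    in the same experiment, averaged.  Day 1 yields no point (no loss is
    defined there).  Cultivars lacking drought or control pots are skipped
    and logged; days with undefined TR are excluded and logged.

    ``ftsw_pairing`` chooses which soil-water state day d's transpiration
    is attributed to: the midpoint of the bounding weighings (``"mid"``,
    the default — the day's cumulative water use reflects the average soil
    water over the interval), the weighing that opened it (``"start"``),
    or the one that closed it (``"end"``).  The one-sided pairings shift
    the apparent breakpoint by up to half a day's drawdown (high for
    ``"start"``, low for ``"end"``).

    ``exclude_exhaustion_day`` drops (and logs) the single day on which a
    pot's FTSW first reaches 0: transpirable water ran out partway through
    that interval, so its loss measures the water that remained, not the
    demand the response curve describes — a censored observation that
    otherwise biases the breakpoint upward for fast-draining pots.  Days
    after exhaustion stay in (their zero NTR at zero FTSW is informative).
    """
    if tr_mode not in ("loss_ratio", "weight_ratio"):
        raise PipelineError(f"unknown tr_mode {tr_mode!r}")
    if ftsw_pairing not in ("start", "end", "mid"):
        raise PipelineError(f"unknown ftsw_pairing {ftsw_pairing!r}")
    df = data.weights if isinstance(data, WeighingDataset) else data
    df = validate_weighing(df)

    points: list[pd.DataFrame] = []
    log: list[dict] = []

    def note(exp, cultivar, rep, day, reason):
        log.append(
            {
                "experiment_id": exp,
                "cultivar": cultivar,
                "replicate": rep,
                "day": day,
                "reason": reason,
            }
        )

    for exp_id, exp in df.groupby("experiment_id", sort=True):
        bare = exp[exp["treatment"] == "bare"]
        if len(bare):
            bare_losses = [
                daily_water_loss(g["day"], g["weight_g"])
                for _, g in bare.groupby("pot_id")
            ]
            bare_mean = pd.concat(bare_losses, axis=1).mean(axis=1)
        else:
            some_days = exp["day"].unique()
            bare_mean = pd.Series(0.0, index=pd.Index(np.sort(some_days)[1:], name="day"))

        plants = exp[exp["treatment"] != "bare"]
        for cultivar, grp in plants.groupby("cultivar", sort=True):
            drought = grp[grp["treatment"] == "drought"]
            controls = grp[grp["treatment"] == "irrigated"]
            if drought.empty:
                note(exp_id, cultivar, None, None, "no drought pots")
                continue
            if controls.empty:
                note(exp_id, cultivar, None, None, "no paired control pots")
                continue

            if tr_mode == "weight_ratio":
                ctrl_weight = controls.groupby("day")["weight_g"].mean()
            else:
                ctrl_losses = [
                    correct_evaporation(
                        daily_water_loss(g["day"], g["weight_g"], rewatered=True),
                        bare_mean,
                    )
                    for _, g in controls.groupby("pot_id")
                ]

            for _, pot in drought.groupby("pot_id"):
                rep = int(pot["replicate"].iloc[0])
                try:
                    ftsw = fraction_tsw(pot["day"], pot["weight_g"])
                    if tr_mode == "weight_ratio":
                        w = pot.set_index("day")["weight_g"]
                        tr = (w / ctrl_weight.reindex(w.index)).iloc[1:].rename("tr")
                    else:
                        loss = correct_evaporation(
                            daily_water_loss(pot["day"], pot["weight_g"]), bare_mean
                        )
                        tr = transpiration_ratio(loss, ctrl_losses)
                    ntr = normalize_ntr(tr, baseline_days)
                except PipelineError as err:
                    note(exp_id, cultivar, rep, None, str(err))
                    continue

                for day in ntr.index:
                    if pd.isna(ntr.loc[day]):
                        note(exp_id, cultivar, rep, int(day), "undefined TR (zero control loss)")
                if exclude_exhaustion_day:
                    exhausted = ftsw.index[(ftsw <= 0.0) & (ftsw.shift(1) > 0.0)]
                    if len(exhausted):
                        d_exh = int(exhausted[0])
                        if d_exh in ntr.index:
                            ntr = ntr.drop(d_exh)
                            note(
                                exp_id, cultivar, rep, d_exh,
                                "exhaustion day: water ran out mid-interval, loss censored",
                            )
                if ftsw_pairing == "start":
                    paired = ftsw.reindex(ntr.index - 1)
                elif ftsw_pairing == "end":
                    paired = ftsw.reindex(ntr.index)
                else:
                    paired = (
                        ftsw.reindex(ntr.index - 1).to_numpy()
                        + ftsw.reindex(ntr.index).to_numpy()
                    ) / 2.0
                joined = pd.DataFrame(
                    {
                        "cultivar": cultivar,
                        "replicate": rep,
                        "day": ntr.index,
                        "ftsw": np.asarray(paired, dtype=float),
                        "ntr": ntr.to_numpy(),
                    }
                ).dropna(subset=["ntr", "ftsw"])
                points.append(joined)

    points_df = (
        pd.concat(points, ignore_index=True)[POINT_COLUMNS]
        if points
        else pd.DataFrame(columns=POINT_COLUMNS)
    )
    log_df = pd.DataFrame(log, columns=LOG_COLUMNS)
    return ResponsePoints(points=points_df, log=log_df)
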