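"""Screen-level decision layer: DMSO normalization, replicate aggregation,
hit calling, artifact filtering and Z'-factor plate QC.

The compound score is the "normalized ER calcium response": a compound
well's mean responsive-cell peak divided by the mean over valid DMSO wells
on the same plate. Compounds whose replicate-mean score falls strictly below
the hit cutoff (0.9 by default) and that carry no artifact flag are hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateQC",
    "normalize_to_dmso",
    "aggregate_replicates",
    "call_hits",
    "flag_artifacts",
    "build_screen_table",
    "zprime",
    "responsive_fraction_report",
]

DEFAULT_HIT_CUTOFF = 0.9
DEFAULT_AUTOFLUOR_K_SD = 5.0
DEFAULT_TOXIC_FRACTION = 0.3

#: Decimal places kept on normalized responses before the strict hit
#: comparison — a guard so compounds sitting numerically on the cutoff are
#: classified by their exact score, not by last-bit float noise.
_SCORE_DECIMALS = 9


def well_results_frame(results, layout=None) -> pd.DataFrame:
    """Tabulate :class:`~fretscreen.traces.WellResult` objects, optionally
    joined with layout columns (role, compound_id, replicate)."""
    df = pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "n_cells": r.n_cells,
                "n_responsive": r.n_responsive,
                "responsive_fraction": r.responsive_fraction,
                "mean_peak_responsive": r.mean_peak_responsive,
                "sd_peak_responsive": r.sd_peak_responsive,
                "valid": r.valid,
                "baseline_donor_mean": r.baseline_donor_mean,
                "baseline_acceptor_mean": r.baseline_acceptor_mean,
            }
            for r in results
        ]
    )
    if layout is not None:
        df = df.merge(layout.to_frame(), on="well_id", how="left")
    return df


def normalize_to_dmso(well_df: pd.DataFrame) -> pd.DataFrame:
    """Divide each valid well's mean responsive peak by the same-plate DMSO
    mean (mean over valid DMSO wells' readouts).

    Requires ``role`` and ``mean_peak_responsive`` columns; a plate with no
    valid DMSO well, or a non-positive DMSO mean, is rejected.
    """
    dmso = well_df[(well_df["role"] == "DMSO") & well_df["valid"]]
    if dmso.empty:
        raise ValueError("plate has no valid DMSO well; cannot normalize")
    dmso_mean = float(dmso["mean_peak_responsive"].mean())
    if not np.isfinite(dmso_mean) or dmso_mean <= 0:
        raise ValueError("DMSO reference mean is not positive")
    out = well_df.copy()
    out["normalized_response"] = np.where(
        out["valid"], out["mean_peak_responsive"] / dmso_mean, np.nan
    )
    return out


def aggregate_replicates(well_df: pd.DataFrame) -> pd.DataFrame:
    """Per-compound mean ± sample sd of normalized response over valid
    replicate wells; invalid replicates are excluded and counted."""
    comp = well_df[well_df["role"] == "compound"]
    rows = []
    for cid, grp in comp.groupby("compound_id", sort=True):
        vals = grp.loc[grp["valid"], "normalized_response"].to_numpy(float)
        rows.append(
            {
                "compound_id": cid,
                "n_replicates": len(grp),
                "n_valid": len(vals),
                "normalized_response_mean": (
                    float(np.mean(vals)) if len(vals) else float("nan")
                ),
                "normalized_response_sd": (
                    float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                )
                if len(vals)
                else float("nan"),
                "unmeasured": len(vals) == 0,
            }
        )
    return pd.DataFrame(rows)


def flag_artifacts(
    well_df: pd.DataFrame,
    k_sd: float = DEFAULT_AUTOFLUOR_K_SD,
    toxic_fraction: float = DEFAULT_TOXIC_FRACTION,
) -> pd.DataFrame:
    """Per-well artifact flags.

    autofluorescent: pre-dispense per-cell donor or acceptor baseline exceeds
    the DMSO-well mean by more than ``k_sd`` DMSO standard deviations.
    toxic: detected cell count below ``toxic_fraction`` of the plate median.
    """
    out = well_df.copy()
    dmso = out[out["role"] == "DMSO"]
    if dmso.empty:
        raise ValueError("artifact flags need DMSO reference wells")
    flags_af = np.zeros(len(out), dtype=bool)
    for col in ("baseline_donor_mean", "baseline_acceptor_mean"):
        mu = float(dmso[col].mean())
        sd = float(dmso[col].std(ddof=1)) if len(dmso) > 1 else 0.0
        flags_af |= out[col].to_numpy(float) > mu + k_sd * sd
    median_cells = float(out["n_cells"].median())
    out["autofluorescent"] = flags_af
    out["toxic"] = out["n_cells"].to_numpy(float) < toxic_fraction * median_cells
    return out


def call_hits(
    screen_df: pd.DataFrame, cutoff: float = DEFAULT_HIT_CUTOFF
) -> pd.DataFrame:
    """Hit iff the replicate-mean normalized response is strictly below the
    cutoff and the compound carries no artifact flag."""
    out = screen_df.copy()
    score = np.round(out["normalized_response_mean"].to_numpy(float), _SCORE_DECIMALS)
    clean = ~(
        out.get("autofluorescent", pd.Series(False, index=out.index)).fillna(False)
        | out.get("toxic", pd.Series(False, index=out.index)).fillna(False)
    )
    out["hit"] = (score < cutoff) & clean.to_numpy(bool)
    return out


def build_screen_table(
    well_df: pd.DataFrame,
    hit_cutoff: float = DEFAULT_HIT_CUTOFF,
    k_sd: float = DEFAULT_AUTOFLUOR_K_SD,
    toxic_fraction: float = DEFAULT_TOXIC_FRACTION,
) -> pd.DataFrame:
    """Well table -> compound screen table: normalize, flag artifacts,
    aggregate replicates, call hits.

    A compound inherits an artifact flag if any of its wells is flagged.
    """
    wells = normalize_to_dmso(well_df)
    wells = flag_artifacts(wells, k_sd=k_sd, toxic_fraction=toxic_fraction)
    table = aggregate_replicates(wells)
    comp = wells[wells["role"] == "compound"]
    flags = comp.groupby("compound_id", sort=True)[["autofluorescent", "toxic"]].any()
    table = table.merge(flags.reset_index(), on="compound_id", how="left")
    return call_hits(table, cutoff=hit_cutoff)


@dataclass
class PlateQC:
    """Control statistics and Z'-factor for one plate.

    ``zprime_canonical`` uses the Zhang et al. screening-window statistic
    1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|; ``zprime_as_printed`` the variant
    1 − (3σ_pos + σ_neg)/|μ_pos − μ_neg| that weights only the positive
    control's spread by 3.
    """

    plate_id: str
    mu_tp: float
    sigma_tp: float
    mu_dmso: float
    sigma_dmso: float
    zprime_canonical: float
    zprime_as_printed: float


def zprime(tp_values, dmso_values, plate_id: str = "", variant: str = "canonical"):
    """Z'-factor from positive (TP) and negative (DMSO) control well values.

    Returns a :class:`PlateQC` carrying both formula variants; ``variant``
    selects which one the scalar helper :func:`zprime_value` reports.
    """
    tp = np.asarray(tp_values, dtype=float)
    dmso = np.asarray(dmso_values, dtype=float)
    if len(tp) < 2 or len(dmso) < 2:
        raise ValueError("need at least two wells per control group")
    if variant not in ("canonical", "as_printed"):
        raise ValueError(f"unknown zprime variant {variant!r}")
    mu_tp, mu_dmso = float(tp.mean()), float(dmso.mean())
    sd_tp = float(tp.std(ddof=1))
    sd_dmso = float(dmso.std(ddof=1))
    sep = abs(mu_tp - mu_dmso)
    if sep == 0:
        raise ValueError("Z' undefined: control means are equal")
    return PlateQC(
        plate_id=plate_id,
        mu_tp=mu_tp,
        sigma_tp=sd_tp,
        mu_dmso=mu_dmso,
        sigma_dmso=sd_dmso,
        zprime_canonical=1.0 - 3.0 * (sd_tp + sd_dmso) / sep,
        zprime_as_printed=1.0 - (3.0 * sd_tp + sd_dmso) / sep,
    )


def zprime_value(tp_values, dmso_values, variant: str = "canonical") -> float:
    qc = zprime(tp_values, dmso_values, variant=variant)
    return qc.zprime_canonical if variant == "canonical" else qc.zprime_as_printed


def responsive_fraction_report(well_df: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Mean ± sd of responsive fraction and responsive-cell peak per
    condition group (e.g. genotype)."""
    rows = []
    for cond, grp in well_df.groupby(by, sort=True):
        frac = grp["responsive_fraction"].to_numpy(float)
        peak = grp["mean_peak_responsive"].to_numpy(float)
        rows.append(
            {
                by: cond,
                "n_wells": len(grp),
                "responsive_fraction_mean": float(np.nanmean(frac)),
                "responsive_fraction_sd": (
                    float(np.nanstd(frac, ddof=1)) if len(grp) > 1 else 0.0
                ),
                "mean_peak_mean": float(np.nanmean(peak)),
                "mean_peak_sd": (
                    float(np.nanstd(peak, ddof=1)) if len(grp) > 1 else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
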