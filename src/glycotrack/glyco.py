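"""Differential T/Tn O-glycoproteomics pipeline.

Quantification is dimethyl isotope-doublet based: each glycopeptide PSM
carries a medium-channel intensity (deuterated formaldehyde label, control
genotype) and a light-channel intensity (formaldehyde label, mutant
genotype).  The working quantity is log10(light/medium) — negative values
mean lower glycosylation in the mutant.  An empirical null is fitted to
flow-through (non-glycosylated) peptide ratios; doublets outside the null's
high-coverage interval (the full-scale flow-through calibration gives +/-0.55 at 99.7%
coverage) are candidate glycosylation changes.  PSMs aggregate to glycosites
(protein accession, 1-based position, residue) and glycosites to proteins,
with fold-change categories at 3x and 10x and a direct-target flag for
proteins where one site drops while another is unchanged or up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "T3_DEFAULT",
    "T10_DEFAULT",
    "COVERAGE_DEFAULT",
    "CATEGORIES",
    "NullRatioModel",
    "UnpairedRecordError",
    "DegenerateInputError",
    "DataIntegrityError",
    "compute_log_ratio",
    "compute_log_ratios",
    "fit_null_model",
    "select_candidates",
    "classify_fold_change",
    "aggregate_glycosites",
    "summarize_proteins",
    "glycoproteome_report",
    "compare_multiplicity",
    "peptide_site_to_protein",
]

#: 3-fold change threshold on |log10 ratio|.
T3_DEFAULT = math.log10(3.0)
#: 10-fold change threshold on |log10 ratio|.
T10_DEFAULT = 1.0
#: Two-sided normal coverage of the null interval; 2*Phi(3)-1, i.e. the
#: "99.7% within +/-0.55" 3-sigma calibration.
COVERAGE_DEFAULT = 0.9973002039367398

CATEGORIES = ("unchanged", "up3", "down3", "up10", "down10", "unquantified")

_CHANGED = {"up3", "down3", "up10", "down10"}
_DOWN = {"down3", "down10"}
_NOT_DOWN = {"unchanged", "up3", "up10"}

RECORD_COLUMNS = [
    "protein_id",
    "peptide",
    "site_position",
    "residue",
    "glycoform",
    "intensity_medium",
    "intensity_light",
    "paired",
]


class UnpairedRecordError(ValueError):
    """The record lacks one channel; its ratio is unquantifiable (distinct
    from a ratio of zero)."""


class DegenerateInputError(ValueError):
    """Too few or zero-variance values to fit the empirical null."""


class DataIntegrityError(ValueError):
    """Inconsistent annotations, e.g. two residue letters at one site key."""


@dataclass(frozen=True)
class NullRatioModel:
    """Empirical null of flow-through log10 ratios.

    mu/sigma are the sample mean/sd; cutoff is the half-width of the
    candidate exclusion interval around mu (default 3*sigma via the
    99.73% two-sided normal quantile).
    """

    mu: float
    sigma: float
    cutoff: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


def compute_log_ratio(record: Mapping) -> float:
    """log10(light/medium) of one paired record: mutant over control."""
    light = record["intensity_light"]
    medium = record["intensity_medium"]
    if (
        not bool(record.get("paired", True))
        or light is None
        or medium is None
        or not np.isfinite(light)
        or not np.isfinite(medium)
    ):
        raise UnpairedRecordError(
            "record has no isotope pair; ratio is unquantifiable"
        )
    if light <= 0 or medium <= 0:
        raise UnpairedRecordError("non-positive intensity; treated as unpaired")
    return math.log10(light / medium)


def compute_log_ratios(records: pd.DataFrame) -> pd.Series:
    """Vectorised log10(light/medium); NaN for unpaired/invalid records."""
    light = pd.to_numeric(records["intensity_light"], errors="coerce")
    medium = pd.to_numeric(records["intensity_medium"], errors="coerce")
    ok = (light > 0) & (medium > 0)
    if "paired" in records:
        ok &= records["paired"].astype(bool)
    out = pd.Series(np.nan, index=records.index, name="log_ratio")
    out[ok] = np.log10(light[ok] / medium[ok])
    return out


def fit_null_model(
    flowthrough_log_ratios: Iterable[float], coverage: float = COVERAGE_DEFAULT
) -> NullRatioModel:
    """Fit the empirical null from flow-through peptide log10 ratios.

    cutoff = z * sigma with z the two-sided normal quantile of ``coverage``
    (z = 3 at the default 99.73% coverage; a study-scale flow-through
    gives cutoff ~ 0.55).
    """
    x = np.asarray(list(flowthrough_log_ratios), float)
    x = x[np.isfinite(x)]
    if x.size < 30:
        raise DegenerateInputError("need at least 30 finite ratios to fit the null")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0:
        raise DegenerateInputError("zero variance: cannot fit null model")
    z = float(stats.norm.ppf(0.5 + coverage / 2.0))
    return NullRatioModel(mu=float(np.mean(x)), sigma=sigma, cutoff=z * sigma)


def select_candidates(
    records: pd.DataFrame, model: NullRatioModel, ratio_column: str = "log_ratio"
) -> pd.DataFrame:
    """Rows whose |log_ratio - mu| strictly exceeds the null cutoff.

    Unquantifiable (NaN-ratio) rows are excluded, never selected.  Boundary
    values (exactly at the cutoff) are excluded.
    """
    if ratio_column not in records:
        records = records.assign(**{ratio_column: compute_log_ratios(records)})
    r = records[ratio_column]
    mask = (r - model.mu).abs() > model.cutoff
    return records.loc[mask.fillna(False)]


def classify_fold_change(
    log_ratio, t3: float = T3_DEFAULT, t10: float = T10_DEFAULT
):
    """Fold-change category of a log10 ratio (scalar or array).

    |r| < t3 -> unchanged; t3 <= |r| < t10 -> up3/down3 by sign;
    |r| >= t10 -> up10/down10.  Down means mutant below control.
    """
    if not 0 < t3 < t10:
        raise ValueError("need 0 < t3 < t10")
    arr = np.asarray(log_ratio, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("log_ratio must be finite")
    a = np.abs(arr)
    up = arr > 0
    cat = np.where(
        a < t3,
        "unchanged",
        np.where(a < t10, np.where(up, "up3", "down3"), np.where(up, "up10", "down10")),
    )
    if np.isscalar(log_ratio) or arr.ndim == 0:
        return str(cat)
    return cat


def _classify_or_unquantified(r: float, t3: float, t10: float) -> str:
    if r is None or not np.isfinite(r):
        return "unquantified"
    return classify_fold_change(r, t3, t10)


def peptide_site_to_protein(peptide_start: int, position_in_peptide: int) -> int:
    """Map a 1-based position within a peptide to the 1-based protein
    coordinate, given the peptide's 1-based start in the protein."""
    if peptide_start < 1 or position_in_peptide < 1:
        raise ValueError("positions are 1-based and must be >= 1")
    return peptide_start + position_in_peptide - 1


def aggregate_glycosites(
    records: pd.DataFrame, t3: float = T3_DEFAULT, t10: float = T10_DEFAULT
) -> pd.DataFrame:
    """Aggregate PSM records to one row per glycosite.

    Site key is (protein_id, site_position, residue).  Per glycoform the
    site ratio is the median of paired-PSM log ratios (robust to outlier
    PSMs); sites whose glycoform has no paired PSM are 'unquantified' for
    that glycoform.  glycoform_class is the union of observed glycoforms
    (paired or not).  Two residue letters at one (protein, position) raise
    DataIntegrityError.
    """
    if records.empty:
        raise ValueError("records table is empty")
    bad_gf = set(records["glycoform"].unique()) - {"Tn", "T"}
    if bad_gf:
        raise DataIntegrityError(f"unknown glycoform values: {sorted(bad_gf)}")
    nres = records.groupby(["protein_id", "site_position"])["residue"].nunique()
    if (nres > 1).any():
        key = nres[nres > 1].index[0]
        raise DataIntegrityError(f"conflicting residue letters at site {key}")

    df = records.copy()
    df["log_ratio"] = compute_log_ratios(df)
    rows = []
    for (pid, pos, res), g in df.groupby(
        ["protein_id", "site_position", "residue"], sort=True
    ):
        forms = set(g["glycoform"])
        gclass = (
            "both" if forms == {"Tn", "T"} else ("Tn-only" if forms == {"Tn"} else "T-only")
        )
        row = {
            "protein_id": pid,
            "site_position": int(pos),
            "residue": res,
            "glycoform_class": gclass,
        }
        for gf in ("Tn", "T"):
            sub = g.loc[(g["glycoform"] == gf) & g["log_ratio"].notna(), "log_ratio"]
            med = float(sub.median()) if len(sub) else np.nan
            row[f"log_ratio_{gf}"] = med
            row[f"n_psm_{gf}"] = int((g["glycoform"] == gf).sum())
            row[f"category_{gf}"] = (
                _classify_or_unquantified(med, t3, t10)
                if gf in forms
                else "unquantified"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_proteins(
    site_table: pd.DataFrame,
    t3: float = T3_DEFAULT,
    t10: float = T10_DEFAULT,
) -> pd.DataFrame:
    """Aggregate glycosites to one row per protein.

    Protein glycoform class is Tn-only/T-only when every site is, else
    'both'.  category derives from the site ratio of largest magnitude
    over both glycoforms; direct_target is True iff some site on the
    protein decreased past the 3x threshold while another site is
    unchanged or increased (a pattern arguing for a glycosylation change
    rather than lower protein expression).
    """
    if site_table.empty:
        raise ValueError("site table is empty")
    rows = []
    for pid, g in site_table.groupby("protein_id", sort=True):
        classes = set(g["glycoform_class"])
        gclass = (
            "Tn-only"
            if classes == {"Tn-only"}
            else ("T-only" if classes == {"T-only"} else "both")
        )
        ratios = g[["log_ratio_Tn", "log_ratio_T"]].to_numpy(float).ravel()
        ratios = ratios[np.isfinite(ratios)]
        if ratios.size:
            extreme = float(ratios[np.argmax(np.abs(ratios))])
            max_abs = abs(extreme)
            category = classify_fold_change(extreme, t3, t10)
        else:
            extreme, max_abs, category = np.nan, np.nan, "unquantified"
        site_cats = g[["category_Tn", "category_T"]]
        down_site = site_cats.isin(_DOWN).any(axis=1)
        ok_site = site_cats.isin(_NOT_DOWN).any(axis=1)
        # distinct sites required: a down site and a different non-down site
        direct = bool(down_site.any() and (ok_site & ~down_site).any())
        rows.append(
            {
                "protein_id": pid,
                "n_glycosites": int(len(g)),
                "glycoform_class": gclass,
                "max_abs_log_ratio": max_abs,
                "category": category,
                "direct_target": direct,
            }
        )
    return pd.DataFrame(rows)


def _round_percentages(values: Mapping[str, float], decimals: int = 0) -> dict:
    """Largest-remainder rounding so each axis sums to exactly 100."""
    keys = list(values)
    raw = np.array([values[k] for k in keys], float)
    if raw.sum() == 0:
        return {k: 0.0 for k in keys}
    scale = 10**decimals
    scaled = raw * scale
    floored = np.floor(scaled)
    short = int(round(100 * scale - floored.sum()))
    order = np.argsort(-(scaled - floored))
    for i in order[:short]:
        floored[i] += 1
    out = floored / scale
    return {k: (float(v) if decimals else int(v)) for k, v in zip(keys, out)}


def glycoproteome_report(
    site_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    t3: float = T3_DEFAULT,
    t10: float = T10_DEFAULT,
    cutoff: float | None = None,
) -> dict:
    """Counts and percentages summarising the glycoproteome.

    Includes totals, glycoform-class composition at site and protein level,
    site-multiplicity distribution, residue composition, counts of proteins
    past the 3x and 10x thresholds (max |ratio| over sites and glycoforms),
    and T-changed vs Tn-changed protein overlap with direction.  Percentages
    use largest-remainder rounding (integer %, residue split at 0.1%).  When
    the candidate ``cutoff`` is given, its fold-equivalent is surfaced so
    the gap between the empirical-null cutoff and the literal 3x bin is
    explicit.
    """
    classes = ("Tn-only", "T-only", "both")
    site_class_counts = {c: int((site_table["glycoform_class"] == c).sum()) for c in classes}
    prot_class_counts = {
        c: int((protein_table["glycoform_class"] == c).sum()) for c in classes
    }
    n_sites = len(site_table)
    n_proteins = len(protein_table)

    mult = protein_table["n_glycosites"].value_counts().sort_index()
    pct_mult = _round_percentages(
        {str(int(k)): 100.0 * v / n_proteins for k, v in mult.items()}
    )
    residue_counts = {
        r: int((site_table["residue"] == r).sum()) for r in ("T", "S", "Y")
    }

    over3 = protein_table["max_abs_log_ratio"] >= t3
    over10 = protein_table["max_abs_log_ratio"] >= t10

    def _direction(g: pd.Series) -> str | None:
        vals = g.to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if not vals.size:
            return None
        ext = vals[np.argmax(np.abs(vals))]
        return "up" if ext > 0 else "down"

    changed = {}
    for gf in ("Tn", "T"):
        cats = site_table[f"category_{gf}"]
        ch = site_table.loc[cats.isin(_CHANGED)]
        per_prot = ch.groupby("protein_id")[f"log_ratio_{gf}"].apply(_direction)
        changed[gf] = per_prot.dropna().to_dict()
    t_set, tn_set = set(changed["T"]), set(changed["Tn"])
    venn = {
        "T_only_changed": len(t_set - tn_set),
        "Tn_only_changed": len(tn_set - t_set),
        "both_changed": len(t_set & tn_set),
        "T_up": sum(1 for v in changed["T"].values() if v == "up"),
        "T_down": sum(1 for v in changed["T"].values() if v == "down"),
        "Tn_up": sum(1 for v in changed["Tn"].values() if v == "up"),
        "Tn_down": sum(1 for v in changed["Tn"].values() if v == "down"),
    }

    unquantified_sites = int(
        (
            (site_table["category_Tn"] == "unquantified")
            & (site_table["category_T"] == "unquantified")
        ).sum()
    )

    report = {
        "n_glycosites": n_sites,
        "n_proteins": n_proteins,
        "site_class_counts": site_class_counts,
        "protein_class_counts": prot_class_counts,
        "pct_sites_by_class": _round_percentages(
            {c: 100.0 * v / n_sites for c, v in site_class_counts.items()}
        ),
        "pct_proteins_by_class": _round_percentages(
            {c: 100.0 * v / n_proteins for c, v in prot_class_counts.items()}
        ),
        "pct_proteins_by_n_sites": pct_mult,
        "residue_counts": residue_counts,
        "pct_residues": _round_percentages(
            {r: 100.0 * v / n_sites for r, v in residue_counts.items()}, decimals=1
        ),
        "n_proteins_over_3x": int(over3.sum()),
        "n_proteins_over_10x": int(over10.sum()),
        "n_direct_targets": int(protein_table["direct_target"].sum()),
        "changed_protein_venn": venn,
        "n_sites_unquantified": unquantified_sites,
        "thresholds": {"t3_log10": t3, "t10_log10": t10, "fold_3x": 10**t3, "fold_10x": 10**t10},
    }
    if cutoff is not None:
        report["candidate_cutoff"] = {
            "log10": cutoff,
            "fold_equivalent": 10**cutoff,
            "note": "empirical-null cutoff differs from the literal 3x bin",
        }
    return report


def compare_multiplicity(
    altered_site_counts: Sequence[int], all_site_counts: Sequence[int]
) -> float:
    """Two-sided Mann-Whitney U p-value comparing glycosites-per-protein of
    the altered protein set against the full glycoproteome (normal
    approximation with tie correction)."""
    x = np.asarray(altered_site_counts, float)
    y = np.asarray(all_site_counts, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)
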