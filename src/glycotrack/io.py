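"""Table and image IO, pipeline configuration, and the end-to-end runner.

Canonical table format is TSV (CSV accepted, chosen by extension), UTF-8,
decimal point.  Glycosite positions are 1-based protein coordinates
(UniProt convention); image pixels are 0-based, origin top-left.  The
glycopeptide reader takes a column map so externally produced tables —
including the deposited supplementary-style layout where glycoforms are
spelled HexNAc / HexHexNAc — can be ingested unmodified.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import glyco
from .tracking import Track

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "GLYCOFORM_ALIASES",
    "read_glycopeptide_table",
    "write_glycopeptide_table",
    "read_tracks",
    "write_tracks",
    "read_image",
    "write_image",
    "write_report",
    "run_pipeline",
]

log = logging.getLogger("glycotrack")

#: Accepted spellings of the two glycoforms (MS search engines report the
#: glycan composition, not the antigen name).
GLYCOFORM_ALIASES = {
    "Tn": "Tn",
    "T": "T",
    "HexNAc": "Tn",
    "HexHexNAc": "T",
    "1xHexNAc": "Tn",
    "1xHexHexNAc": "T",
}

_MANDATORY = [
    "protein_id",
    "peptide",
    "site_position",
    "residue",
    "glycoform",
    "intensity_medium",
    "intensity_light",
]


class SchemaError(ValueError):
    """The table is missing mandatory columns or is unreadable."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_glycopeptide_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a PSM-level glycopeptide table.

    ``column_map`` maps canonical field names to the file's column names
    (fields absent from the map use their canonical name).  Returns
    ``(records, rejects)``: validated records with a derived ``paired``
    flag, and the malformed rows with a ``reject_reason`` column.
    Missing mandatory columns raise SchemaError.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    if raw.empty:
        raise SchemaError(f"{path} contains no data rows")
    column_map = dict(column_map or {})
    rename = {}
    for canon in _MANDATORY:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise SchemaError(f"missing mandatory column {src!r} (for {canon!r})")
        rename[src] = canon
    df = raw.rename(columns=rename)[_MANDATORY].copy()

    df["glycoform"] = df["glycoform"].map(
        lambda v: GLYCOFORM_ALIASES.get(str(v).strip(), None)
    )
    df["site_position"] = pd.to_numeric(df["site_position"], errors="coerce")
    df["intensity_medium"] = pd.to_numeric(df["intensity_medium"], errors="coerce")
    df["intensity_light"] = pd.to_numeric(df["intensity_light"], errors="coerce")

    reasons = pd.Series("", index=df.index)

    def _flag(mask: pd.Series, reason: str) -> None:
        nonlocal reasons
        add = mask & (reasons == "")
        reasons[add] = reason

    _flag(df["protein_id"].isna() | (df["protein_id"].astype(str).str.strip() == ""),
          "missing protein_id")
    _flag(~df["residue"].isin(["S", "T", "Y"]), "residue not one of S/T/Y")
    _flag(df["glycoform"].isna(), "unrecognized glycoform")
    _flag(df["site_position"].isna() | (df["site_position"] < 1)
          | (df["site_position"] % 1 != 0), "invalid site_position")
    # medium channel (control) is mandatory; light may be absent (singleton)
    _flag(df["intensity_medium"].isna() | (df["intensity_medium"] <= 0),
          "missing or non-positive medium intensity")
    _flag(df["intensity_light"].notna() & (df["intensity_light"] <= 0),
          "non-positive light intensity")

    bad = reasons != ""
    rejects = raw.loc[bad].copy()
    rejects["reject_reason"] = reasons[bad]
    records = df.loc[~bad].copy()
    records["site_position"] = records["site_position"].astype(int)
    records["paired"] = records["intensity_light"].notna()
    log.info(
        "read_glycopeptide_table path=%s rows=%d accepted=%d rejected=%d",
        path, len(raw), len(records), len(rejects),
    )
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


def write_glycopeptide_table(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    records.to_csv(path, sep=_sep_for(path), index=False)
    return path


_TRACK_COLUMNS = ["track_id", "frame", "t_seconds", "x_um", "y_um", "z_um"]


def read_tracks(path: str | Path) -> list[Track]:
    """Read tracks from a delimited table with columns track_id, frame,
    t_seconds, x_um, y_um, z_um; rows are sorted by frame within track."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = set(_TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"track table missing columns: {sorted(missing)}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(
            Track(
                track_id=str(tid),
                times=g["t_seconds"].to_numpy(float),
                positions=g[["x_um", "y_um", "z_um"]].to_numpy(float),
            )
        )
    log.info("read_tracks path=%s tracks=%d rows=%d", path, len(tracks), len(df))
    return tracks


def write_tracks(tracks: Sequence[Track], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": i,
                    "t_seconds": tr.times[i],
                    "x_um": tr.positions[i, 0],
                    "y_um": tr.positions[i, 1],
                    "z_um": tr.positions[i, 2],
                }
            )
    pd.DataFrame(rows, columns=_TRACK_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read a single- or multi-channel raster (TIFF or PNG) as float."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), float)
    import imageio.v3 as iio

    return np.asarray(iio.imread(path), float)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(image))
    else:
        import imageio.v3 as iio

        arr = np.asarray(image)
        if arr.dtype.kind == "f":  # PNG needs integers
            arr = np.clip(arr, 0, 65535).astype(np.uint16)
        iio.imwrite(path, arr)
    return path


def _flatten(d: Mapping, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, Mapping):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out


def write_report(report: Mapping, basepath: str | Path) -> tuple[Path, Path]:
    """Write a report as ``<base>.json`` and a flattened ``<base>.tsv``."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    jpath = base.with_suffix(".json")
    with open(jpath, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    tpath = base.with_suffix(".tsv")
    flat = _flatten(report)
    with open(tpath, "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        for k in sorted(flat):
            fh.write(f"{k}\t{flat[k]}\n")
    return jpath, tpath


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end glycoproteomics run.

    Either ``flowthrough_path`` (a one-column table of null log10 ratios to
    fit the empirical null from) or ``cutoff_override`` (a fixed half-width,
    e.g. the 0.55 calibration) must be provided.
    """

    glyco_table: str
    out_dir: str
    flowthrough_path: str | None = None
    cutoff_override: float | None = None
    t3: float = glyco.T3_DEFAULT
    t10: float = glyco.T10_DEFAULT
    coverage: float = glyco.COVERAGE_DEFAULT
    column_map: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flowthrough_path is None and self.cutoff_override is None:
            raise ValueError("provide flowthrough_path or cutoff_override")
        for name in ("t3", "t10"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def run_pipeline(config: PipelineConfig) -> dict:
    """Ingest -> null fit -> ratios -> candidates -> site/protein summaries
    -> report; writes all artifacts under ``config.out_dir`` and returns the
    report dict (with a config echo for provenance).  Deterministic for a
    fixed config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, rejects = read_glycopeptide_table(config.glyco_table, config.column_map)
    if records.empty:
        raise SchemaError("no valid records after validation")
    rejects.to_csv(out / "rejects.tsv", sep="\t", index=False)

    if config.flowthrough_path is not None:
        ft = pd.read_csv(config.flowthrough_path, sep=_sep_for(Path(config.flowthrough_path)))
        model = glyco.fit_null_model(ft.iloc[:, 0].to_numpy(float), config.coverage)
        log.info("fit_null_model n=%d mu=%.4g sigma=%.4g cutoff=%.4g",
                 len(ft), model.mu, model.sigma, model.cutoff)
    else:
        model = glyco.NullRatioModel(mu=0.0, sigma=config.cutoff_override / 3.0,
                                     cutoff=config.cutoff_override)
        log.info("null model from cutoff override %.4g", config.cutoff_override)

    records = records.assign(log_ratio=glyco.compute_log_ratios(records))
    candidates = glyco.select_candidates(records, model)
    log.info("select_candidates in=%d paired=%d candidates=%d",
             len(records), int(records["log_ratio"].notna().sum()), len(candidates))
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)

    site_table = glyco.aggregate_glycosites(records, config.t3, config.t10)
    protein_table = glyco.summarize_proteins(site_table, config.t3, config.t10)
    log.info("aggregate sites=%d proteins=%d", len(site_table), len(protein_table))
    site_table.to_csv(out / "glycosites.tsv", sep="\t", index=False)
    protein_table.to_csv(out / "proteins.tsv", sep="\t", index=False)

    report = glyco.glycoproteome_report(
        site_table, protein_table, config.t3, config.t10, cutoff=model.cutoff
    )
    report["n_records"] = int(len(records))
    report["n_unpaired_records"] = int((~records["paired"]).sum())
    report["n_rejected_rows"] = int(len(rejects))
    report["n_candidates"] = int(len(candidates))
    report["null_model"] = {"mu": model.mu, "sigma": model.sigma, "cutoff": model.cutoff}
    report["config"] = dataclasses.asdict(config)
    write_report(report, out / "report")
    return report
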