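"""Batch pipeline: join molecular-species-level annotations with OAD spectra,
annotate C=C positions, and write a result table.

The CID-level input is a tab-delimited alignment export (one row per aligned
feature: lipid name, precursor m/z, retention time, adduct); OAD spectra come
from MGF or mzML. Records and spectra are integrated on precursor m/z
(0.01 Da) and retention time (0.15 min) windows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import base64
import struct
import zlib
import xml.etree.ElementTree as _ET

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .config import Config
from .matching import AnnotationOutcome, MeasuredSpectrum, annotate_species
from .nomenclature import LipidNameError, parse_lipid_name
from .registry import SubclassRegistry, default_registry
from .rules import FragmentRule, default_rules

logger = logging.getLogger("oadlipid")

#: header synonyms accepted for each mandatory alignment-table column
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "lipid_name": ("Metabolite name", "lipid_name", "Name", "metabolite_name"),
    "precursor_mz": ("Average Mz", "precursor_mz", "Precursor m/z", "mz"),
    "retention_time": (
        "Average Rt(min)", "retention_time", "RT (min)", "rt", "rt_min",
    ),
    "adduct": ("Adduct type", "adduct", "Adduct", "Precursor type"),
}


@dataclass(frozen=True)
class AlignmentRecord:
    record_id: str
    lipid_name: str
    precursor_mz: float
    retention_time: float
    adduct: str
    extras: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class AnnotationResult:
    record: AlignmentRecord
    status: str  # resolved|ambiguous|chain-unresolved|unresolved|no-spectrum
    resolved_name: str | None
    score: float | None
    outcome: AnnotationOutcome | None = None
    note: str = ""


def _resolve_columns(columns: list[str]) -> dict[str, str]:
    mapping = {}
    missing = []
    for canon, synonyms in COLUMN_SYNONYMS.items():
        for syn in synonyms:
            if syn in columns:
                mapping[canon] = syn
                break
        else:
            missing.append(canon)
    if missing:
        raise ValueError(
            f"alignment table is missing mandatory columns {missing}; "
            f"accepted headers: "
            f"{ {k: list(v) for k, v in COLUMN_SYNONYMS.items()} }"
        )
    return mapping


def read_alignment_table(
    path: str | Path, registry: SubclassRegistry | None = None
) -> list[AlignmentRecord]:
    """Read a tab-delimited alignment export; malformed rows are skipped."""
    registry = registry or default_registry()
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = _resolve_columns(list(df.columns))
    records: list[AlignmentRecord] = []
    n_skipped = 0
    for i, row in df.iterrows():
        name = str(row[mapping["lipid_name"]])
        try:
            parse_lipid_name(name, registry)
            rec = AlignmentRecord(
                record_id=str(row.get("id", i)),
                lipid_name=name,
                precursor_mz=float(row[mapping["precursor_mz"]]),
                retention_time=float(row[mapping["retention_time"]]),
                adduct=str(row[mapping["adduct"]]),
                extras={
                    k: row[k] for k in df.columns
                    if k not in mapping.values() and k != "id"
                },
            )
        except (LipidNameError, ValueError, KeyError) as exc:
            n_skipped += 1
            logger.warning("skipping row %s (%r): %s", i, name, exc)
            continue
        records.append(rec)
    if n_skipped:
        logger.info("skipped %d unparseable rows", n_skipped)
    return records


def read_spectra(path: str | Path, fmt: str | None = None) -> list[MeasuredSpectrum]:
    """Read centroided MS/MS spectra from MGF or mzML."""
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if path.suffix.lower() == ".mzml" else "mgf"
    fmt = fmt.lower()
    if fmt == "mgf":
        return _read_mgf(path)
    if fmt == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unsupported spectrum format {fmt!r} (use mgf or mzml)")


def _read_mgf(path: Path) -> list[MeasuredSpectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            pep = params.get("pepmass")
            if pep is None or pep[0] is None:
                logger.warning("spectrum %d lacks precursor m/z; skipped", i)
                continue
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else None
            spectra.append(MeasuredSpectrum(
                precursor_mz=float(pep[0]),
                retention_time=rt_min,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                spectrum_id=str(params.get("title", i)),
            ))
    return spectra


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv_params(elem) -> dict[str, tuple[str, str]]:
    """name -> (value, unitName) over the element's direct cvParam children."""
    out = {}
    for cv in elem.findall(f"{_MZML_NS}cvParam"):
        out[cv.get("name")] = (cv.get("value", ""), cv.get("unitName", ""))
    return out


def _decode_binary_array(array_elem) -> np.ndarray:
    params = _cv_params(array_elem)
    binary = array_elem.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(binary.text or "")
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    width = "f" if "32-bit float" in params else "d"
    return np.asarray(struct.unpack(f"<{len(raw) // struct.calcsize(width)}{width}", raw))


def _read_mzml(path: Path) -> list[MeasuredSpectrum]:
    """Minimal mzML reader (MS2 scans, 32/64-bit float arrays, optional
    zlib compression); written in-package because no suitable mzML parser
    is available as a dependency."""
    spectra = []
    tree = _ET.parse(str(path))
    for i, spec in enumerate(tree.iter(f"{_MZML_NS}spectrum")):
        params = _cv_params(spec)
        if params.get("ms level", ("",))[0] != "2":
            continue
        ion = spec.find(
            f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
            f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
        )
        prec_mz = None
        if ion is not None:
            val = _cv_params(ion).get("selected ion m/z")
            prec_mz = float(val[0]) if val else None
        if prec_mz is None:
            logger.warning("MS2 scan %d lacks precursor m/z; skipped", i)
            continue
        rt_min = None
        scan = spec.find(f"{_MZML_NS}scanList/{_MZML_NS}scan")
        if scan is not None:
            val = _cv_params(scan).get("scan start time")
            if val:
                rt_min = float(val[0])
                if val[1] == "second":
                    rt_min /= 60.0
        mz = inten = None
        for arr in spec.findall(
            f"{_MZML_NS}binaryDataArrayList/{_MZML_NS}binaryDataArray"
        ):
            names = _cv_params(arr)
            if "m/z array" in names:
                mz = _decode_binary_array(arr)
            elif "intensity array" in names:
                inten = _decode_binary_array(arr)
        if mz is None or inten is None:
            logger.warning("MS2 scan %d lacks peak arrays; skipped", i)
            continue
        spectra.append(MeasuredSpectrum(
            precursor_mz=prec_mz,
            retention_time=rt_min,
            mz=mz,
            intensity=inten,
            spectrum_id=str(spec.get("id", i)),
        ))
    return spectra


def join_cid_oad(
    records: list[AlignmentRecord],
    spectra: list[MeasuredSpectrum],
    mz_tol_da: float = 0.01,
    rt_tol_min: float = 0.15,
) -> list[tuple[AlignmentRecord, MeasuredSpectrum | None]]:
    """Pair each record with the nearest-precursor spectrum within both
    windows (|Δm/z| first, |ΔRT| as tie-break); unmatched records pair None."""
    if mz_tol_da <= 0 or rt_tol_min <= 0:
        raise ValueError("tolerances must be > 0")
    pairs = []
    for rec in records:
        best: MeasuredSpectrum | None = None
        best_key: tuple[float, float] | None = None
        for sp in spectra:
            if sp.retention_time is None:
                continue  # excluded from RT joins
            dmz = abs(sp.precursor_mz - rec.precursor_mz)
            drt = abs(sp.retention_time - rec.retention_time)
            if dmz <= mz_tol_da and drt <= rt_tol_min:
                key = (dmz, drt)
                if best_key is None or key < best_key:
                    best, best_key = sp, key
        pairs.append((rec, best))
    return pairs


def annotate_batch(
    pairs: list[tuple[AlignmentRecord, MeasuredSpectrum | None]],
    config: Config | None = None,
    rules: tuple[FragmentRule, ...] | None = None,
    registry: SubclassRegistry | None = None,
    log_path: str | Path | None = None,
) -> list[AnnotationResult]:
    """Run the annotation over joined (record, spectrum) units.

    Per-record failures are captured as unresolved results with a note; the
    batch continues. An optional JSON-lines log records per-record candidate
    counts, survivors and scores.
    """
    cfg = config or Config()
    rules = rules or default_rules()
    registry = registry or default_registry()
    results: list[AnnotationResult] = []
    log_fh = open(log_path, "w") if log_path else None
    try:
        for rec, spectrum in pairs:
            if spectrum is None:
                results.append(AnnotationResult(rec, "no-spectrum", None, None))
                continue
            try:
                species = parse_lipid_name(rec.lipid_name, registry,
                                           adduct=rec.adduct)
                outcome = annotate_species(species, spectrum, rules, cfg, registry)
                name = outcome.resolved_name
                if (
                    cfg.demote_plasmalogen_pc and name
                    and name.startswith("PC P-")
                ):
                    name = "PC O-" + name[len("PC P-"):]
                results.append(AnnotationResult(
                    rec, outcome.status, name, outcome.score, outcome
                ))
            except Exception as exc:  # per-record isolation
                logger.warning("record %s failed: %s", rec.record_id, exc)
                results.append(AnnotationResult(
                    rec, "unresolved", None, None, note=f"error: {exc}"
                ))
            if log_fh is not None:
                last = results[-1]
                log_fh.write(json.dumps({
                    "record_id": rec.record_id,
                    "input_name": rec.lipid_name,
                    "status": last.status,
                    "resolved_name": last.resolved_name,
                    "score": last.score,
                    "n_candidates": (
                        last.outcome.n_candidates if last.outcome else 0
                    ),
                }) + "\n")
    finally:
        if log_fh is not None:
            log_fh.close()
    return results


def results_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        out = res.outcome
        rows.append({
            "record_id": res.record.record_id,
            "input_name": res.record.lipid_name,
            "precursor_mz": f"{res.record.precursor_mz:.4f}",
            "retention_time": f"{res.record.retention_time:.3f}",
            "adduct": res.record.adduct,
            "resolved_name": res.resolved_name or "",
            "status": res.status,
            "score": "" if res.score is None else f"{res.score:.6f}",
            "n_candidates": out.n_candidates if out else 0,
            "tied_candidates": ";".join(out.tied_names) if out else "",
            "ambiguous_positions": (out.ambiguous_label or "") if out else "",
            "diagnostic_ions": ";".join(out.evidence) if out else "",
            "note": res.note,
        })
    return pd.DataFrame(rows, columns=[
        "record_id", "input_name", "precursor_mz", "retention_time", "adduct",
        "resolved_name", "status", "score", "n_candidates", "tied_candidates",
        "ambiguous_positions", "diagnostic_ions", "note",
    ])


def write_results(results: list[AnnotationResult], path: str | Path) -> None:
    """Write one row per input record, tab-delimited, bit-stable across runs."""
    results_frame(results).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
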