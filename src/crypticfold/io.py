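"""File formats at the package boundary.

Curves travel as delimited text (CSV) with ``#key=value`` metadata
header lines; temperatures are degrees Celsius in files and Kelvin in
memory.  Kinetic parameters, fit results and overlap reports are JSON.
Sequences use FASTA (via biotite), conformer ensembles multi-model PDB.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult
from .kinetics import BarrierReport, ExperimentCurve, KineticParams

C0 = 273.15  # K at 0 degC


def write_curve(curve: ExperimentCurve, path) -> None:
    """Write a curve as CSV with metadata headers (temperatures in degC)."""
    path = Path(path)
    lines = [f"#technique={curve.technique}"]
    if curve.name:
        lines.append(f"#name={curve.name}")
    if curve.technique == "ISOTHERMAL":
        lines.append(f"#hold_T_C={curve.hold_temperature - C0:.6g}")
        x_out = curve.x  # minutes
        xlab = "time_min"
    else:
        lines.append(f"#scan_rate_C_per_min={curve.scan_rate:.6g}")
        x_out = curve.x - C0
        xlab = "temperature_C"
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        fh.write(f"{xlab},y\n")
        for xv, yv in zip(x_out, curve.y):
            fh.write(f"{xv:.8g},{yv:.8g}\n")


def read_curve(path) -> ExperimentCurve:
    """Read a metadata-headed curve CSV written by :func:`write_curve`."""
    meta = {}
    rows = []
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            elif not header_seen:
                header_seen = True
            else:
                rows.append([float(v) for v in line.split(",")])
    if "technique" not in meta:
        raise ValueError(f"{path}: missing #technique header")
    data = np.asarray(rows)
    tech = meta["technique"]
    kwargs = {"name": meta.get("name", Path(path).stem)}
    if tech == "ISOTHERMAL":
        kwargs["hold_temperature"] = float(meta["hold_T_C"]) + C0
        x = data[:, 0]
    else:
        kwargs["scan_rate"] = float(meta["scan_rate_C_per_min"])
        x = data[:, 0] + C0
    return ExperimentCurve(technique=tech, x=x, y=data[:, 1], **kwargs)


def params_to_json(params: KineticParams, path=None) -> str:
    text = json.dumps(params.as_dict(), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def params_from_json(source) -> KineticParams:
    if isinstance(source, (str, Path)) and Path(source).exists():
        data = json.loads(Path(source).read_text())
    else:
        data = json.loads(source)
    return KineticParams(**data)


def fit_result_to_json(result: FitResult, path=None) -> str:
    text = json.dumps(result.as_dict(), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def barrier_report_to_frame(report: BarrierReport) -> pd.DataFrame:
    """Barrier table with both K and degC columns, kJ/mol energies."""
    return pd.DataFrame({
        "temperature_K": report.temperatures,
        "temperature_C": report.temperatures - C0,
        "dG1_kJ_mol": report.dG1,
        "dG2_kJ_mol": report.dG2,
    })


def read_profile(path, value_column: str = "score") -> np.ndarray:
    """Per-residue profile from delimited text (residue_index, value).

    Rows may arrive unsorted; residue indices must be 1..n without gaps.
    """
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    idx_col = cols.get("residue_index", df.columns[0])
    val_col = cols.get(value_column, df.columns[1])
    df = df.sort_values(idx_col)
    idx = df[idx_col].to_numpy()
    if not np.array_equal(idx, np.arange(1, idx.size + 1)):
        raise ValueError(f"{path}: residue_index must be 1..n without gaps")
    return df[val_col].to_numpy(dtype=float)


def write_profile(values, path, value_column: str = "score") -> None:
    pd.DataFrame({
        "residue_index": np.arange(1, len(values) + 1),
        value_column: values,
    }).to_csv(path, index=False)


def read_fasta(path) -> dict[str, str]:
    import biotite.sequence.io.fasta as fasta

    ff = fasta.FastaFile.read(str(path))
    return {name: str(seq) for name, seq in ff.items()}


def write_fasta(records: dict[str, str], path) -> None:
    import biotite.sequence.io.fasta as fasta

    ff = fasta.FastaFile()
    for name, seq in records.items():
        ff[name] = seq
    ff.write(str(path))


def write_ensemble_pdb(frames, path) -> None:
    """Write StructureFrame conformers as a multi-model Cα-bead PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    from .tables import THREE_TO_ONE

    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    arrays = []
    for fr in frames:
        n = fr.coords.shape[0]
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(fr.coords, dtype=np.float32)
        arr.chain_id = np.full(n, "A")
        arr.res_id = fr.residue_index
        arr.res_name = np.array([one_to_three.get(t, "UNK") for t in fr.residue_type])
        arr.atom_name = np.full(n, "CA")
        arr.element = np.full(n, "C")
        arr.hetero = np.zeros(n, dtype=bool)
        arrays.append(arr)
    pdbf = pdb.PDBFile()
    pdbf.set_structure(struc.stack(arrays))
    pdbf.write(str(path))
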