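"""File readers and writers for all analysis stages.

Tables travel as TSV/CSV (pandas), coordinates as standard multi-model
PDB (gemmi).  Readers validate against the domain-type invariants and
report malformed content with the offending line or row.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .ensemble import CoordinateEnsemble
from .errors import ParseError
from .exchange import IntensitySeries
from .rdc import BondVectorSet, RdcSet
from .spr import BindingIsotherm

__all__ = [
    "read_intensity_table",
    "write_intensity_table",
    "read_spr_csv",
    "write_spr_csv",
    "read_rdc_table",
    "write_rdc_table",
    "read_vector_table",
    "write_vector_table",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "write_spectrum_tsv",
]

_PEAKS = ("AA", "BB", "AB", "BA")


def _read_table(path, sep, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise ParseError(f"{path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_intensity_table(path, label: str | None = None) -> IntensitySeries:
    """Read an Nz-exchange intensity table.

    Expected TSV columns: label, delay_s, peak (AA|BB|AB|BA), intensity,
    sigma (optional).  One row per peak per delay.
    """
    df = _read_table(path, "\t", {"label", "delay_s", "peak", "intensity"})
    if label is not None:
        df = df[df["label"] == label]
        if df.empty:
            raise ParseError(f"{path}: no rows with label {label!r}")
    elif df["label"].nunique() > 1:
        raise ParseError(
            f"{path}: multiple labels {sorted(df['label'].unique())}; pass label="
        )
    bad = ~df["peak"].isin(_PEAKS)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based + header
        raise ParseError(f"{path}: line {row}: peak must be one of {_PEAKS}")
    dup = df.duplicated(subset=["delay_s", "peak"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}: line {row}: duplicate (delay, peak) row")
    pivot = df.pivot(index="delay_s", columns="peak", values="intensity").sort_index()
    if pivot.isna().any().any():
        raise ParseError(f"{path}: incomplete peak quartets at some delays")
    sigma = None
    if "sigma" in df.columns and df["sigma"].notna().all():
        sig = df.pivot(index="delay_s", columns="peak", values="sigma").sort_index()
        sigma = sig.mean(axis=1).to_numpy()
    return IntensitySeries(
        delays=pivot.index.to_numpy(dtype=float),
        i_aa=pivot["AA"].to_numpy(), i_bb=pivot["BB"].to_numpy(),
        i_ab=pivot["AB"].to_numpy(), i_ba=pivot["BA"].to_numpy(),
        sigma=sigma, label=str(df["label"].iloc[0]),
    )


def write_intensity_table(series: IntensitySeries, path) -> None:
    rows = []
    for i, d in enumerate(series.delays):
        for peak, arr in zip(_PEAKS, (series.i_aa, series.i_bb, series.i_ab, series.i_ba)):
            rows.append({
                "label": series.label or "series",
                "delay_s": d,
                "peak": peak,
                "intensity": arr[i],
                "sigma": series.sigma[i] if series.sigma is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spr_csv(path, variant: str | None = None) -> BindingIsotherm:
    """Read a steady-state SPR table: variant, concentration_uM, response_RU."""
    df = _read_table(path, ",", {"variant", "concentration_uM", "response_RU"})
    if variant is not None:
        df = df[df["variant"] == variant]
        if df.empty:
            raise ParseError(f"{path}: no rows for variant {variant!r}")
    elif df["variant"].nunique() > 1:
        raise ParseError(
            f"{path}: multiple variants {sorted(df['variant'].unique())}; pass variant="
        )
    return BindingIsotherm(
        concentrations=df["concentration_uM"].to_numpy(dtype=float),
        responses=df["response_RU"].to_numpy(dtype=float),
        variant=str(df["variant"].iloc[0]),
    )


def write_spr_csv(iso: BindingIsotherm, path) -> None:
    pd.DataFrame({
        "variant": iso.variant or "isotherm",
        "concentration_uM": iso.concentrations,
        "response_RU": iso.responses,
    }).to_csv(path, index=False)


def read_rdc_table(path) -> RdcSet:
    """Read an RDC table: residue, d_obs_hz, sigma_hz (optional)."""
    df = _read_table(path, "\t", {"residue", "d_obs_hz"})
    sigma = df["sigma_hz"].to_numpy(dtype=float) if "sigma_hz" in df.columns else None
    return RdcSet(
        residues=df["residue"].to_numpy(dtype=int),
        d=df["d_obs_hz"].to_numpy(dtype=float),
        sigma=sigma,
    )


def write_rdc_table(rdcs: RdcSet, path) -> None:
    data = {"residue": rdcs.residues, "d_obs_hz": rdcs.d}
    if rdcs.sigma is not None:
        data["sigma_hz"] = rdcs.sigma
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_vector_table(path) -> BondVectorSet:
    """Read unit bond vectors: residue, x, y, z."""
    df = _read_table(path, "\t", {"residue", "x", "y", "z"})
    return BondVectorSet(
        residues=df["residue"].to_numpy(dtype=int),
        vectors=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_vector_table(vectors: BondVectorSet, path) -> None:
    pd.DataFrame({
        "residue": vectors.residues,
        "x": vectors.vectors[:, 0],
        "y": vectors.vectors[:, 1],
        "z": vectors.vectors[:, 2],
    }).to_csv(path, sep="\t", index=False)


def bond_vectors_from_ensemble(
    ens: CoordinateEnsemble,
    model: int = 0,
    atom_a: str = "N",
    atom_b: str = "H",
    place_missing_h: bool = True,
) -> BondVectorSet:
    """Unit vectors atom_a -> atom_b per residue from one model.

    For the default amide N-H selection, residues whose proton is absent
    (common in X-ray models) get an idealized in-plane H placed along the
    external bisector of the CA-N and C(prev)-N directions; a warning
    reports how many protons were placed.  Residues still missing either
    atom are skipped.
    """
    pos: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    want = {atom_a, atom_b, "CA", "C"}
    for idx, (chain, res, atom, _elem) in enumerate(ens.roster):
        if atom in want:
            pos.setdefault((chain, res), {})[atom] = ens.coords[model, idx]
    placed = 0
    if atom_b == "H" and place_missing_h:
        for (chain, res), atoms in pos.items():
            if "H" in atoms or "N" not in atoms or "CA" not in atoms:
                continue
            prev = pos.get((chain, res - 1))
            if prev is None or "C" not in prev:
                continue
            n = atoms["N"]
            u = atoms["CA"] - n
            v = prev["C"] - n
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            d = -(u + v)
            norm = np.linalg.norm(d)
            if norm > 1e-9:
                atoms["H"] = n + 1.02 * d / norm
                placed += 1
    if placed:
        warnings.warn(f"placed {placed} idealized amide protons", stacklevel=2)
    residues, vecs = [], []
    for (chain, res), atoms in sorted(pos.items()):
        if atom_a in atoms and atom_b in atoms:
            v = atoms[atom_b] - atoms[atom_a]
            norm = np.linalg.norm(v)
            if norm > 0:
                residues.append(res)
                vecs.append(v / norm)
    if not residues:
        raise ParseError(f"no {atom_a}-{atom_b} pairs found in ensemble")
    return BondVectorSet(residues=np.array(residues), vectors=np.array(vecs))


def read_pdb_ensemble(path) -> CoordinateEnsemble:
    """Read a multi-model PDB file (MODEL/ENDMDL blocks; first altloc kept).

    All models must share one (chain, residue, atom) roster; a mismatch
    raises a parse error naming the offending model.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    st = gemmi.read_structure(os.fspath(path))
    st.remove_alternative_conformations()
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    roster = None
    all_coords = []
    for imodel, model in enumerate(st, start=1):
        this_roster, coords = [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    this_roster.append(
                        (chain.name, residue.seqid.num, atom.name, atom.element.name)
                    )
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if roster is None:
            roster = this_roster
        elif this_roster != roster:
            raise ParseError(
                f"{path}: model {imodel} atom roster differs from model 1"
            )
        all_coords.append(coords)
    return CoordinateEnsemble(
        roster=roster, coords=np.array(all_coords, dtype=float), source=str(path)
    )


def write_pdb_ensemble(ens: CoordinateEnsemble, path) -> None:
    """Write a minimal multi-model PDB file."""
    with open(path, "w") as fh:
        for m in range(ens.n_models):
            fh.write(f"MODEL     {m + 1:4d}\n")
            serial = 0
            for (chain, res, atom, elem), (x, y, z) in zip(
                ens.roster, ens.coords[m]
            ):
                serial += 1
                name = atom if len(atom) >= 4 else f" {atom:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} UNK {chain:>1s}{res:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {elem:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_spectrum_tsv(spec, path) -> None:
    pd.DataFrame({"freq_hz": spec.freqs, "intensity": spec.intensity}).to_csv(
        path, sep="\t", index=False
    )
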