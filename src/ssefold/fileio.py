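"""File formats: PDB coordinates, secondary structure predictions, pool
files, DSSP-style assignments, trajectory and metrics tables.

Coordinates go through gemmi.  Only ATOM records with the five backbone
slots (N, CA, C, O, CB) are used; glycine's pseudo-CB is written with atom
name HA2 (its geometric stand-in) and mapped back to the CB slot on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .geometry import ATOMS, ProteinModel, build_ideal_sse, derive_frame
from .pool import PoolEntry, SSEPool, SSPrediction, PoolError

AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

TRAJECTORY_HEADER = "#ssefold-trajectory-v1"


class FileFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


@dataclass
class PdbChain:
    """Backbone coordinates read from a PDB file."""

    indices: np.ndarray   # 1-based residue numbers, sorted
    restypes: str         # one-letter codes
    coords: np.ndarray    # (n, 5, 3)


def _atom_name(slot: int, restype: str) -> str:
    name = ATOMS[slot]
    if name == "CB" and restype == "G":
        return "HA2"
    return name


def write_pdb(target, path) -> None:
    """Write a ProteinModel or any object with (sequence, coords, mask)."""
    st = gemmi.Structure()
    st.name = "ssefold"
    mdl = gemmi.Model("1")
    chain = gemmi.Chain("A")
    if isinstance(target, ProteinModel):
        items = [
            (idx, target.sequence[idx - 1], sse.coords[k])
            for sse in target.sses
            for k, idx in enumerate(sse.residue_indices)
        ]
    else:  # BuiltStructure-like: full coords
        items = [
            (i + 1, target.sequence[i], target.coords[i])
            for i in range(len(target.sequence))
            if np.isfinite(target.coords[i]).all()
        ]
    for idx, aa, xyz in items:
        res = gemmi.Residue()
        res.name = AA1_TO_3[aa.upper()]
        res.seqid = gemmi.SeqId(int(idx), " ")
        for slot in range(5):
            atom = gemmi.Atom()
            atom.name = _atom_name(slot, aa.upper())
            atom.element = gemmi.Element("H" if atom.name.startswith("H") else atom.name[0])
            atom.pos = gemmi.Position(*xyz[slot])
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        chain.add_residue(res)
    mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def read_pdb(path, chain_name: str | None = None) -> PdbChain:
    """Read backbone coordinates; residues missing N/CA/C/O are excluded
    with a warning (a missing CB/HA2 is tolerated and back-filled NaN)."""
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FileFormatError(f"{path}: no models")
    mdl = st[0]
    if chain_name is None:
        if len(mdl) != 1:
            raise FileFormatError(
                f"{path}: {len(mdl)} chains; pass an explicit chain name"
            )
        chain = mdl[0]
    else:
        chain = mdl[chain_name]
        if chain is None:
            raise FileFormatError(f"{path}: no chain {chain_name!r}")
    indices, restypes, coords = [], [], []
    skipped = 0
    for res in chain:
        aa = AA3_TO_1.get(res.name)
        if aa is None:
            continue
        xyz = np.full((5, 3), np.nan)
        for atom in res:
            name = atom.name
            if name == "HA2" and aa == "G":
                name = "CB"
            if name in ATOMS:
                slot = ATOMS.index(name)
                xyz[slot] = [atom.pos.x, atom.pos.y, atom.pos.z]
        if not np.isfinite(xyz[:4]).all():
            skipped += 1
            continue
        indices.append(res.seqid.num)
        restypes.append(aa)
        coords.append(xyz)
    if skipped:
        warnings.warn(f"{path}: excluded {skipped} residue(s) with missing "
                      "backbone atoms")
    if not indices:
        raise FileFormatError(f"{path}: no usable residues")
    order = np.argsort(indices)
    return PdbChain(
        np.asarray(indices)[order],
        "".join(restypes[i] for i in order),
        np.asarray(coords)[order],
    )


def model_from_pdb(path, pool: SSEPool, sequence: str | None = None) -> ProteinModel:
    """Reconstruct an SSE-only ProteinModel from a PDB written by this
    package plus the pool entries describing its SSE bounds/types."""
    pdb = read_pdb(path)
    idx_of = {int(i): k for k, i in enumerate(pdb.indices)}
    if sequence is None:
        # build a sparse sequence: unknown gaps filled with alanine
        L = int(pdb.indices.max())
        seq = ["A"] * L
        for i, aa in zip(pdb.indices, pdb.restypes):
            seq[int(i) - 1] = aa
        sequence = "".join(seq)
    sses = []
    for e in pool:
        if e.first not in idx_of or e.last not in idx_of:
            continue
        rows = [idx_of[i] for i in range(e.first, e.last + 1)]
        coords = pdb.coords[rows]
        if not np.isfinite(coords).all():
            continue
        frame = derive_frame(coords, e.ss_type)
        sse = build_ideal_sse(
            sequence[e.first - 1 : e.last], e.first, e.last, e.ss_type
        ).transformed(frame)
        sses.append(sse)
    return ProteinModel(sequence, sses, provenance=pool.source)


# ---------------------------------------------------------------------------
# Secondary structure predictions
# ---------------------------------------------------------------------------


def _check_probs(rows, path):
    idx = [r[0] for r in rows]
    if idx != list(range(1, len(idx) + 1)):
        raise FileFormatError(f"{path}: residue indices not contiguous from 1")
    probs = np.array([r[2] for r in rows], dtype=float)
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 0.02):
        bad = int(np.argmax(np.abs(sums - 1.0))) + 1
        raise FileFormatError(
            f"{path}: probabilities at residue {bad} sum to {sums[bad-1]:.3f}"
        )
    probs /= sums[:, None]
    seq = "".join(r[1] for r in rows)
    return seq, probs


def read_ss2(path):
    """PSIPRED .ss2: `idx aa state pC pH pE`; returns (sequence, (L,3) array
    with columns p_helix, p_strand, p_coil)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 6:
                raise FileFormatError(f"{path}:{lineno}: expected 6 columns")
            try:
                idx = int(parts[0])
                p_c, p_h, p_e = (float(x) for x in parts[3:6])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append((idx, parts[1], (p_h, p_e, p_c)))
    if not rows:
        raise FileFormatError(f"{path}: empty prediction")
    return _check_probs(rows, path)


def read_pred_tsv(path):
    """Generic prediction TSV: `idx aa pH pE pC` (JUFO-style dialect)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 5:
                raise FileFormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                idx = int(parts[0])
                p_h, p_e, p_c = (float(x) for x in parts[2:5])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append((idx, parts[1], (p_h, p_e, p_c)))
    if not rows:
        raise FileFormatError(f"{path}: empty prediction")
    return _check_probs(rows, path)


def load_predictions(ss2_path=None, tsv_path=None) -> SSPrediction:
    methods = {}
    if ss2_path is not None:
        _, probs = read_ss2(ss2_path)
        methods["psipred"] = probs
    if tsv_path is not None:
        _, probs = read_pred_tsv(tsv_path)
        methods["jufo"] = probs
    if not methods:
        raise FileFormatError("no prediction files given")
    return SSPrediction(methods)


def write_ss2(path, sequence, probs):
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (ssefold)\n\n")
        for i, aa in enumerate(sequence):
            h, e, c = probs[i]
            state = "C" if c >= max(h, e) else ("H" if h >= e else "E")
            fh.write(f"{i+1:4d} {aa} {state}  {c:6.3f} {h:6.3f} {e:6.3f}\n")


def write_pred_tsv(path, sequence, probs):
    with open(path, "w") as fh:
        for i, aa in enumerate(sequence):
            h, e, c = probs[i]
            fh.write(f"{i+1}\t{aa}\t{h:.3f}\t{e:.3f}\t{c:.3f}\n")


# ---------------------------------------------------------------------------
# Pool files and assignments
# ---------------------------------------------------------------------------


def write_pool(pool: SSEPool, path) -> None:
    with open(path, "w") as fh:
        for e in pool:
            fh.write(f"{e.ss_type.upper()} {e.first} {e.last}\n")


def read_pool(path) -> SSEPool:
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 3 or parts[0] not in ("HELIX", "STRAND"):
                raise FileFormatError(
                    f"{path}:{lineno}: expected 'HELIX|STRAND first last'"
                )
            try:
                first, last = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
            entries.append(PoolEntry(parts[0].lower(), first, last))
    if not entries:
        raise FileFormatError(f"{path}: empty pool")
    try:
        return SSEPool(entries, source=str(path))
    except PoolError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_assignment(path, labels) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(labels, 1):
            fh.write(f"{i} {s}\n")


def read_assignment(path) -> np.ndarray:
    """DSSP-style per-residue assignment: `idx state` with state H/E/C."""
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 2 or parts[1] not in ("H", "E", "C"):
                raise FileFormatError(f"{path}:{lineno}: expected 'idx H|E|C'")
            if int(parts[0]) != len(labels) + 1:
                raise FileFormatError(f"{path}:{lineno}: indices not contiguous")
            labels.append(parts[1])
    if not labels:
        raise FileFormatError(f"{path}: empty assignment")
    return np.asarray(labels)


# ---------------------------------------------------------------------------
# Trajectories, breakdowns, manifests
# ---------------------------------------------------------------------------


def write_trajectory(trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write(TRAJECTORY_HEADER + "\n")
        fh.write("step\tmove\toutcome\te_new\te_best\ttemperature\n")
        for rec in trajectory:
            fh.write(
                f"{rec.step}\t{rec.move}\t{rec.outcome}\t"
                f"{rec.e_new:.6g}\t{rec.e_best:.6g}\t{rec.temperature:.6g}\n"
            )


def read_trajectory(path):
    with open(path) as fh:
        first = fh.readline().strip()
        if first != TRAJECTORY_HEADER:
            raise FileFormatError(f"{path}: not a trajectory file (header {first!r})")
    df = pd.read_csv(path, sep="\t", skiprows=1)
    return list(df.itertuples(index=False))


def write_breakdown(breakdown, path) -> None:
    rows = [
        {"term": k, "raw": breakdown.raw[k], "weighted": breakdown.weighted[k]}
        for k in breakdown.raw
    ]
    rows.append({"term": "total", "raw": "", "weighted": breakdown.total})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(path, seed: int, config) -> None:
    with open(path, "w") as fh:
        fh.write(f"seed: {seed}\nconfig_hash: {config.digest()}\n")


def read_benchmark_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
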