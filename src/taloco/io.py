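"""Readers and writers for every external artifact.

Canonical on-disk formats are plain text: a long CSV for landmarks
(specimen_id, landmark_index, x, y, z), a per-element CSV for stress
fields (element_id, von_mises, volume), Newick for the phylogeny and a
flat CSV for specimen metadata.  A TPS-style landmark reader is
provided as a convenience.  Every reader validates before returning;
validation failures raise and never hand back partial data.
Coordinates and stresses are carried in the units supplied (mm and MPa
assumed); units are configuration metadata only.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .fea import StressField
from .shape import LandmarkSet

logger = logging.getLogger("taloco")

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_landmarks_tps",
    "read_stress_field",
    "write_stress_field",
    "read_tree",
    "write_tree",
    "read_specimen_table",
    "write_specimen_table",
    "validate_specimen_table",
]

LOCOMOTOR_CLASSES = ("leaper", "arboreal_quadruped", "clamber_suspensory")


# -- landmarks ---------------------------------------------------------------

def read_landmarks(path: str | Path, columns: dict[str, str] | None = None) -> list[LandmarkSet]:
    """Read a long-format landmark CSV into one LandmarkSet per specimen.

    ``columns`` optionally remaps the expected column names
    (specimen_id, landmark_index, x, y, z) onto the file's own header.
    Specimens appear in file order; all must share the same landmark
    count.
    """
    colmap = {
        "specimen_id": "specimen_id",
        "landmark_index": "landmark_index",
        "x": "x",
        "y": "y",
        "z": "z",
    }
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"landmark file missing columns: {missing}")
    out = []
    k_expected = None
    for sid, sub in df.groupby(colmap["specimen_id"], sort=False):
        sub = sub.sort_values(colmap["landmark_index"])
        coords = sub[[colmap["x"], colmap["y"], colmap["z"]]].to_numpy(dtype=float)
        if k_expected is None:
            k_expected = coords.shape[0]
        elif coords.shape[0] != k_expected:
            raise ValueError(
                f"specimen {sid!r} has {coords.shape[0]} landmarks; "
                f"expected {k_expected}"
            )
        out.append(LandmarkSet(coords=coords, specimen_id=str(sid)))
    if not out:
        raise ValueError("landmark file contains no specimens")
    logger.info("read %d landmark sets (k=%d) from %s", len(out), k_expected, path)
    return out


def write_landmarks(landmarks: list[LandmarkSet], path: str | Path) -> None:
    rows = []
    for lm in landmarks:
        for i, (x, y, z) in enumerate(lm.coords, start=1):
            rows.append(
                {"specimen_id": lm.specimen_id, "landmark_index": i, "x": x, "y": y, "z": z}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_landmarks_tps(path: str | Path) -> list[LandmarkSet]:
    """Minimal TPS-dialect reader: LM3=<k> blocks of x y z lines, with
    an optional ID=<name> line per block."""
    out = []
    coords: list[list[float]] = []
    k = 0
    sid = None

    def flush() -> None:
        nonlocal coords, k, sid
        if k:
            if len(coords) != k:
                raise ValueError(
                    f"specimen {sid or len(out) + 1}: expected {k} landmarks, "
                    f"got {len(coords)}"
                )
            out.append(
                LandmarkSet(coords=np.asarray(coords), specimen_id=sid or f"specimen_{len(out) + 1}")
            )
        coords = []
        k = 0
        sid = None

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            flush()
            k = int(line.split("=", 1)[1])
        elif upper.startswith("ID="):
            sid = line.split("=", 1)[1].strip()
        elif "=" in line:
            continue  # other TPS keys (IMAGE=, SCALE=...) ignored
        else:
            coords.append([float(v) for v in line.split()])
    flush()
    if not out:
        raise ValueError("TPS file contains no specimens")
    ks = {lm.k for lm in out}
    if len(ks) > 1:
        raise ValueError(f"mixed landmark counts in TPS file: {sorted(ks)}")
    return out


# -- stress fields -----------------------------------------------------------

def read_stress_field(
    path: str | Path,
    specimen_id: str | None = None,
    columns: dict[str, str] | None = None,
) -> StressField:
    """Read one per-element stress table (element_id, von_mises, volume)."""
    colmap = {"element_id": "element_id", "von_mises": "von_mises", "volume": "volume"}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"stress file missing columns: {missing}")
    if df.empty:
        raise ValueError("stress table is empty")
    sid = specimen_id if specimen_id is not None else Path(path).stem
    try:
        return StressField(
            sigma=df[colmap["von_mises"]].to_numpy(dtype=float),
            vol=df[colmap["volume"]].to_numpy(dtype=float),
            element_ids=df[colmap["element_id"]].to_numpy(),
            specimen_id=sid,
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_stress_field(fld: StressField, path: str | Path) -> None:
    pd.DataFrame(
        {"element_id": fld.element_ids, "von_mises": fld.sigma, "volume": fld.vol}
    ).to_csv(path, index=False, float_format="%.17g")


# -- phylogeny ---------------------------------------------------------------

def read_tree(path_or_newick: str | Path) -> dendropy.Tree:
    """Read a rooted Newick phylogeny; polytomies preserved.

    Accepts a file path or a Newick string.  Duplicate tip labels and
    negative branch lengths are hard errors.
    """
    text = str(path_or_newick)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderError as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    logger.info("read tree with %d tips", len(labels))
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


def match_species_to_tips(tree: dendropy.Tree, species: list[str]) -> dict[str, str]:
    """Exact string match (after whitespace trimming) of species names
    to tip labels; any unmatched species is a hard error."""
    tips = {leaf.taxon.label.strip(): leaf.taxon.label for leaf in tree.leaf_node_iter()}
    out = {}
    for sp in species:
        key = sp.strip()
        if key not in tips:
            raise ValueError(f"species {sp!r} has no matching tip in the tree")
        out[sp] = tips[key]
    return out


# -- specimen metadata -------------------------------------------------------

def validate_specimen_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"specimen_id", "species", "locomotor_class", "body_mass_g", "is_fossil"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen ids: {dupes}")
    if (df["body_mass_g"] <= 0).any():
        raise ValueError("body_mass_g must be positive")
    df = df.copy()
    df["is_fossil"] = df["is_fossil"].astype(bool)
    extant = df[~df["is_fossil"]]
    bad_class = extant.loc[
        ~extant["locomotor_class"].isin(LOCOMOTOR_CLASSES), "specimen_id"
    ].tolist()
    if extant["locomotor_class"].isna().any() or bad_class:
        raise ValueError(
            f"extant specimens need a valid locomotor_class; offending: {bad_class}"
        )
    return df


def read_specimen_table(path: str | Path) -> pd.DataFrame:
    return validate_specimen_table(pd.read_csv(path))


def write_specimen_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# -- dataset directories -----------------------------------------------------

def write_dataset(bundle, outdir: str | Path) -> Path:
    """Write a complete dataset (tree, landmarks, per-specimen stress
    tables, metadata, manifest) as a directory of text artifacts."""
    import json

    outdir = Path(outdir)
    (outdir / "stress").mkdir(parents=True, exist_ok=True)
    write_tree(bundle.tree, outdir / "tree.nwk")
    write_landmarks(bundle.landmarks, outdir / "landmarks.csv")
    write_specimen_table(bundle.metadata, outdir / "metadata.csv")
    for sid, fld in bundle.stress_fields.items():
        write_stress_field(fld, outdir / "stress" / f"{sid}.csv")
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    return outdir


def load_dataset(indir: str | Path):
    """Inverse of ``write_dataset``; returns a Bundle."""
    import json

    from .synthetic import Bundle

    indir = Path(indir)
    metadata = read_specimen_table(indir / "metadata.csv")
    manifest = json.loads((indir / "manifest.json").read_text())
    stress_fields = {
        sid: read_stress_field(indir / "stress" / f"{sid}.csv", specimen_id=sid)
        for sid in metadata["specimen_id"]
    }
    return Bundle(
        tree=read_tree(indir / "tree.nwk"),
        landmarks=read_landmarks(indir / "landmarks.csv"),
        stress_fields=stress_fields,
        metadata=metadata,
        fossil_truth=manifest.get("fossil_truth", {}),
        manifest=manifest,
    )
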