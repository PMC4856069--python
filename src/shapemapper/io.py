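"""File formats: cross CSVs, landmark tables, TPS files, meshes, matrices.

The cross dialect mirrors the two-file "csvs" layout used by classical QTL
software: a genotype file whose header rows carry marker name, chromosome
and cM position for each marker column, and a phenotype file keyed by
specimen id holding covariates and (optionally) vectorized landmark
coordinates. All writers round-trip bit-exactly with their readers for data
this package generates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import trimesh

from .genoprob import AA, AB, MISSING, CrossData, GeneticMap
from .morpho.base import LandmarkSample

__all__ = [
    "write_cross_csv",
    "read_cross_csv",
    "write_landmark_csv",
    "read_landmark_csv",
    "write_tps_file",
    "read_tps_file",
    "write_mesh",
    "read_mesh",
    "write_cov_csv",
    "read_cov_csv",
]

_GENO_TO_STR = {AA: "AA", AB: "AB", MISSING: "-"}
_STR_TO_GENO = {"AA": AA, "AB": AB, "H": AB, "-": MISSING, "NA": MISSING, "": MISSING}

COVARIATE_NAMES = ("logCS", "sex", "cross_direction")


def write_cross_csv(cross: CrossData, geno_path, pheno_path) -> None:
    """Write the two-file cross layout (genotypes + phenotypes/covariates)."""
    gmap = cross.genetic_map
    names, chroms, poss = [], [], []
    for chrom, (mnames, mpos) in gmap.chromosomes.items():
        names.extend(mnames)
        chroms.extend([chrom] * len(mnames))
        poss.extend(f"{p:.6g}" for p in mpos)
    with open(geno_path, "w") as fh:
        fh.write("id," + ",".join(names) + "\n")
        fh.write("," + ",".join(chroms) + "\n")
        fh.write("," + ",".join(poss) + "\n")
        for i, ident in enumerate(cross.ids):
            codes = (_GENO_TO_STR[int(g)] for g in cross.genotypes[i])
            fh.write(ident + "," + ",".join(codes) + "\n")

    frames = []
    if cross.covariates is not None:
        frames.append(cross.covariates.reset_index(drop=True))
    pheno = cross.phenotypes
    if pheno is not None:
        if isinstance(pheno, LandmarkSample):
            cols = pheno.coordinate_labels()
            frames.append(pd.DataFrame(pheno.vectorized(), columns=cols))
        else:
            arr = np.asarray(pheno, dtype=float)
            frames.append(
                pd.DataFrame(arr, columns=[f"trait{j + 1}" for j in range(arr.shape[1])])
            )
    df = pd.concat(frames, axis=1) if frames else pd.DataFrame(index=range(cross.n))
    df.insert(0, "id", cross.ids)
    df.to_csv(pheno_path, index=False, float_format="%.12g")


def read_cross_csv(geno_path, pheno_path) -> CrossData:
    """Read the two-file cross layout back into a CrossData.

    Genotype strings map AA -> AA, AB/H -> AB and -/NA/blank -> missing;
    unknown codes are reported with their line number. Phenotype rows are
    aligned to genotype rows by id. Columns named ``<label>_<x|y|z>`` are
    folded back into an n x k x d landmark array.
    """
    with open(geno_path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        chrow = fh.readline().rstrip("\n").split(",")
        posrow = fh.readline().rstrip("\n").split(",")
        if header[0] != "id" or chrow[0] != "" or posrow[0] != "":
            raise ValueError("malformed genotype header rows")
        marker_names = header[1:]
        marker_chrom = chrow[1:]
        marker_pos = [float(p) for p in posrow[1:]]
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=4):
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(header):
                raise ValueError(f"line {lineno}: wrong number of fields")
            ids.append(parts[0])
            row = []
            for col, tok in enumerate(parts[1:], start=1):
                try:
                    row.append(_STR_TO_GENO[tok.strip()])
                except KeyError:
                    raise ValueError(
                        f"line {lineno}, column {col}: unknown genotype code {tok!r}"
                    ) from None
            rows.append(row)

    chroms: dict[str, tuple[list[str], list[float]]] = {}
    for name, chrom, pos in zip(marker_names, marker_chrom, marker_pos):
        chroms.setdefault(chrom, ([], []))
        chroms[chrom][0].append(name)
        chroms[chrom][1].append(pos)
    gmap = GeneticMap({c: (n, np.asarray(p)) for c, (n, p) in chroms.items()})
    genotypes = np.asarray(rows, dtype=np.int8)

    pheno_df = pd.read_csv(pheno_path)
    if "id" not in pheno_df.columns:
        raise ValueError("phenotype file lacks an id column")
    pheno_df["id"] = pheno_df["id"].astype(str)
    missing_ids = set(ids) - set(pheno_df["id"])
    if missing_ids:
        raise ValueError(f"phenotype file is missing ids: {sorted(missing_ids)[:5]}")
    pheno_df = pheno_df.set_index("id").loc[ids].reset_index()

    cov_cols = [c for c in COVARIATE_NAMES if c in pheno_df.columns]
    covariates = pheno_df[cov_cols].copy() if cov_cols else None
    if covariates is not None:
        covariates.index = ids

    trait_cols = [c for c in pheno_df.columns if c not in ("id", *cov_cols)]
    phenotypes = None
    if trait_cols:
        axis_suffix = [c.rsplit("_", 1) for c in trait_cols]
        if all(len(s) == 2 and s[1] in ("x", "y", "z") for s in axis_suffix):
            labels = list(dict.fromkeys(s[0] for s in axis_suffix))
            d = len({s[1] for s in axis_suffix})
            arr = pheno_df[trait_cols].to_numpy(float).reshape(len(ids), len(labels), d)
            phenotypes = LandmarkSample(coords=arr, ids=list(ids), labels=labels)
        else:
            phenotypes = pheno_df[trait_cols].to_numpy(float)

    return CrossData(
        genetic_map=gmap,
        genotypes=genotypes,
        ids=list(ids),
        phenotypes=phenotypes,
        covariates=covariates,
    )


def write_landmark_csv(sample: LandmarkSample, path) -> None:
    """One row per specimen; columns are labeled coordinate triples."""
    df = pd.DataFrame(sample.vectorized(), columns=sample.coordinate_labels())
    df.insert(0, "id", sample.ids)
    df.to_csv(path, index=False, float_format="%.12g")


def read_landmark_csv(path) -> LandmarkSample:
    df = pd.read_csv(path)
    ids = df["id"].astype(str).tolist()
    coord_cols = [c for c in df.columns if c != "id"]
    suffixes = sorted({c.rsplit("_", 1)[1] for c in coord_cols})
    d = len(suffixes)
    labels = list(dict.fromkeys(c.rsplit("_", 1)[0] for c in coord_cols))
    arr = df[coord_cols].to_numpy(float).reshape(len(ids), len(labels), d)
    return LandmarkSample(coords=arr, ids=ids, labels=labels)


def write_tps_file(sample: LandmarkSample, path) -> None:
    """TPS dialect: LM= / LM3= count, coordinate lines, ID= per specimen."""
    tag = "LM3" if sample.d == 3 else "LM"
    with open(path, "w") as fh:
        for i in range(sample.n):
            fh.write(f"{tag}={sample.k}\n")
            for row in sample.coords[i]:
                fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")
            fh.write(f"ID={sample.ids[i]}\n")


def read_tps_file(path) -> LandmarkSample:
    coords, ids = [], []
    current: list[list[float]] | None = None
    expect = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                expect = int(line.split("=", 1)[1])
                current = []
            elif upper.startswith("ID="):
                ids.append(line.split("=", 1)[1])
            else:
                if current is None:
                    raise ValueError("coordinate line before LM= header")
                current.append([float(t) for t in line.split()])
                if len(current) == expect:
                    coords.append(current)
                    current = None
    if not coords:
        raise ValueError("no configurations found")
    while len(ids) < len(coords):
        ids.append(f"spec{len(ids) + 1:04d}")
    return LandmarkSample(coords=np.asarray(coords, dtype=float), ids=ids)


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """PLY (ascii) or OBJ export chosen by the file extension."""
    path = str(path)
    if path.endswith(".ply"):
        data = trimesh.exchange.ply.export_ply(mesh, encoding="ascii")
        with open(path, "wb") as fh:
            fh.write(data)
    else:
        mesh.export(path)


def read_mesh(path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh", process=False)
    return mesh


def write_cov_csv(matrix, path) -> None:
    from .gmatrix import CovMatrix

    if isinstance(matrix, CovMatrix):
        df = pd.DataFrame(matrix.matrix, index=matrix.labels, columns=matrix.labels)
    else:
        df = pd.DataFrame(np.asarray(matrix))
    df.to_csv(path, float_format="%.12g")


def read_cov_csv(path, kind: str = "G"):
    from .gmatrix import CovMatrix

    df = pd.read_csv(path, index_col=0)
    return CovMatrix(df.to_numpy(float), labels=list(df.columns), kind=kind)
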