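"""Flat-file readers and writers.

Formats (all delimited text, diffable):

* map file — CSV ``chrom,marker,pos_cM`` preceded by a mandatory
  ``# design: achiasmate|chiasmate`` comment recording the cross design;
* genotype matrix — CSV, rows = individuals (first column ``id``),
  columns = markers, cells in {2, 1, 0, NA};
* phenotype file — CSV ``id,sex,y`` with sex in {1, 2};
* truth file — JSON with the generating architecture and realized random
  effects of a simulated population.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cross import CrossPopulation
from .genmap import Chromosome, GeneticMap, MapError

__all__ = [
    "SchemaError",
    "read_map",
    "write_map",
    "read_cross",
    "write_cross",
    "write_truth",
    "write_scan_profile",
    "detections_to_records",
    "epistases_to_records",
]


class SchemaError(ValueError):
    """Input file violates the declared schema (message names the cell)."""


def write_map(gmap, path, design="achiasmate"):
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# design: {design}\n")
        fh.write("chrom,marker,pos_cM\n")
        for chrom in gmap.chromosomes:
            for marker, pos in zip(chrom.markers, chrom.positions):
                fh.write(f"{chrom.name},{marker},{pos:g}\n")


def read_map(path):
    """Returns (GeneticMap, design tag)."""
    path = Path(path)
    design = None
    with path.open() as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "design:" in first:
            design = first.split("design:", 1)[1].strip()
        else:
            raise SchemaError(
                f"{path}: missing '# design: ...' header comment"
            )
        df = pd.read_csv(fh)
    if list(df.columns) != ["chrom", "marker", "pos_cM"]:
        raise SchemaError(
            f"{path}: expected header chrom,marker,pos_cM; got {list(df.columns)}"
        )
    if design not in ("achiasmate", "chiasmate"):
        raise SchemaError(f"{path}: unknown design tag {design!r}")
    chroms = []
    for name, sub in df.groupby("chrom", sort=False):
        try:
            chroms.append(Chromosome(
                name=str(name),
                markers=tuple(str(m) for m in sub["marker"]),
                positions=sub["pos_cM"].to_numpy(dtype=float),
            ))
        except MapError as err:
            raise SchemaError(f"{path}: {err}") from err
    try:
        gmap = GeneticMap(chromosomes=tuple(chroms))
    except MapError as err:
        raise SchemaError(f"{path}: {err}") from err
    return gmap, design


def _write_geno(pop, path):
    df = pd.DataFrame(pop.geno.astype(object), columns=pop.map.marker_ids)
    df = df.mask(df < 0, "NA")
    df.insert(0, "id", pop.ids)
    df.to_csv(path, index=False)


def _read_geno(path, gmap):
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "id":
        raise SchemaError(f"{path}: first column must be 'id'")
    markers = list(df.columns[1:])
    expected = gmap.marker_ids
    if markers != expected:
        missing = set(expected) - set(markers)
        extra = set(markers) - set(expected)
        raise SchemaError(
            f"{path}: marker columns do not match the map "
            f"(missing {sorted(missing)[:5]}, unexpected {sorted(extra)[:5]}, "
            "or wrong order)"
        )
    geno = np.empty((len(df), len(markers)), dtype=np.int8)
    for j, m in enumerate(markers):
        col = df[m].str.strip()
        for i, val in enumerate(col):
            if val in ("NA", "", "nan"):
                geno[i, j] = -1
            elif val in ("0", "1", "2"):
                geno[i, j] = int(val)
            else:
                raise SchemaError(
                    f"{path}: unknown genotype code {val!r} at row "
                    f"{df['id'][i]!r}, column {m!r} (allowed: 2, 1, 0, NA)"
                )
    return list(df["id"]), geno


def _write_pheno(pop, path):
    pd.DataFrame({"id": pop.ids, "sex": pop.sex, "y": pop.y}).to_csv(
        path, index=False)


def _read_pheno(path):
    df = pd.read_csv(path, dtype={"id": str})
    if list(df.columns) != ["id", "sex", "y"]:
        raise SchemaError(f"{path}: expected header id,sex,y")
    try:
        sex = df["sex"].astype(int).to_numpy()
    except (TypeError, ValueError) as err:
        raise SchemaError(f"{path}: non-integer sex label") from err
    if not set(np.unique(sex)) <= {1, 2}:
        raise SchemaError(f"{path}: sex labels must be 1 or 2")
    y = pd.to_numeric(df["y"], errors="coerce").to_numpy()
    if np.isnan(y).any():
        bad = df["id"][np.isnan(y)].iloc[0]
        raise SchemaError(f"{path}: non-numeric phenotype for id {bad!r}")
    return list(df["id"]), sex, y


def read_cross(map_path, geno_path, pheno_path):
    """Load and validate a population from the three flat files."""
    gmap, design = read_map(map_path)
    ids_g, geno = _read_geno(geno_path, gmap)
    ids_p, sex, y = _read_pheno(pheno_path)
    if ids_g != ids_p:
        raise SchemaError(
            "genotype and phenotype files list different individuals "
            f"(first mismatch near {next((a for a, b in zip(ids_g, ids_p) if a != b), '?')!r})"
        )
    return CrossPopulation(map=gmap, geno=geno, sex=sex, y=y,
                           design=design, ids=ids_g)


def write_cross(pop, outdir, prefix="population"):
    """Write map/genotype/phenotype (and truth, if any) files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": outdir / f"{prefix}.map.csv",
        "geno": outdir / f"{prefix}.geno.csv",
        "pheno": outdir / f"{prefix}.pheno.csv",
    }
    write_map(pop.map, paths["map"], design=pop.design)
    _write_geno(pop, paths["geno"])
    _write_pheno(pop, paths["pheno"])
    if pop.truth is not None:
        paths["truth"] = outdir / f"{prefix}.truth.json"
        write_truth(pop.truth, paths["truth"])
    return paths


def write_truth(truth, path):
    cfg = truth["config"]
    eff = truth["sex_effects"]
    payload = {
        "seed": truth["seed"],
        "design": cfg.design,
        "mu": cfg.mu,
        "n": cfg.n,
        "qtls": [vars(q) for q in cfg.qtls],
        "epistases": [vars(e) for e in cfg.epistases],
        "variance": vars(cfg.variance),
        "sex_effects": {k: np.asarray(v).tolist()
                        for k, v in vars(eff).items()},
        "qtl_genotypes": {k: v.tolist()
                          for k, v in truth["qtl_geno"].items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_scan_profile(profile, path):
    table = profile.table.copy()
    table["threshold"] = profile.threshold
    table.to_csv(path, index=False)


def detections_to_records(detections):
    return [{
        "chrom": d.chrom, "pos_cM": d.pos_cM, "F": d.F,
        "interval": list(d.interval),
        "a_by_sex": np.asarray(d.a_by_sex).tolist(),
        "d_by_sex": np.asarray(d.d_by_sex).tolist(),
        "a": d.a, "d": d.d,
    } for d in detections]


def epistases_to_records(detections):
    return [{
        "chrom_i": d.chrom_i, "pos_i": d.pos_i,
        "chrom_j": d.chrom_j, "pos_j": d.pos_j, "F": d.F,
        "aa": d.aa, "ad": d.ad, "da": d.da, "dd": d.dd,
    } for d in detections]
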