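"""Tab-separated file formats for maps, genotypes, phenotypes and results.

All files are TSV with an optional block of ``#``-prefixed metadata lines
(config, seed) before the header, so every result file is self-describing.
Genotype files accept two code dialects — letters {A, B, -} or numbers
{2, 0, -1} — normalized internally to {+1, -1, missing}.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .linkage import GeneticMap
from .simulate import MarkerGenotypes, PhenotypeMatrix, QTLArchitecture

__all__ = ["read_map", "read_genotypes", "read_phenotypes", "read_architecture",
           "read_inputs", "write_map", "write_genotypes", "write_phenotypes",
           "write_architecture", "write_table", "RunConfig",
           "convert_icimapping_project"]


@dataclass
class RunConfig:
    """Run configuration mirroring the CLI flags; YAML round-trippable.

    Defaults reproduce the benchmark simulation settings: 1 cM scan step,
    stepwise entry/removal probabilities 0.001/0.002, genome-wide alpha 0.05.
    """

    map_path: str = ""
    genotype_path: str = ""
    phenotype_path: str = ""
    output_path: str = "profile.tsv"
    population: str = "DH"
    p_in: float = 0.001
    p_out: float = 0.002
    step: float = 1.0
    alpha_g: float = 0.05
    seed: int = 0
    likelihood: str = "product"        # or "printed-sum"
    thresholds: str = "formula"        # or "permutation"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def convert_icimapping_project(path):
    """Converter stub for QTL IciMapping native project files.

    The native binary project format is not parsed; export the map, genotype
    and phenotype sheets to TSV in the dialects documented in this module and
    load them with :func:`read_inputs` instead.
    """
    raise NotImplementedError(
        "native QTL IciMapping project files are not parsed; export the map, "
        "genotype and phenotype tables to TSV and use read_inputs()"
    )

_LETTER_CODES = {"A": 1.0, "B": -1.0, "-": np.nan}
_NUMBER_CODES = {"2": 1.0, "0": -1.0, "-1": np.nan}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, na_values=[])


def read_map(path) -> GeneticMap:
    """Read a genetic map: TSV with columns marker, chromosome, position_cM."""
    df = _read_tsv(path)
    missing = {"marker", "chromosome", "position_cM"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: map file lacks columns {sorted(missing)}")
    df["position_cM"] = df["position_cM"].astype(float)
    return GeneticMap(df)


def read_genotypes(path, gmap: GeneticMap | None = None) -> MarkerGenotypes:
    """Read a genotype matrix: first column individual id, one column per marker."""
    df = _read_tsv(path)
    markers = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape)
    codes = _LETTER_CODES if np.isin(raw, list(_LETTER_CODES)).any() else _NUMBER_CODES
    for (i, j), v in np.ndenumerate(raw):
        v = str(v).strip()
        if v not in codes:
            raise ValueError(
                f"{path}: unknown genotype code {v!r} at row {i + 2}, marker {markers[j]} "
                "(heterozygote or foreign codes are illegal in two-class populations)"
            )
        values[i, j] = codes[v]
    geno = MarkerGenotypes(values, markers)
    if gmap is not None and markers != gmap.marker_names:
        raise ValueError(f"{path}: genotype markers do not match the map")
    return geno


def read_phenotypes(path) -> PhenotypeMatrix:
    """Read phenotypes: first column individual id, one column per environment; NA allowed."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA", "nan", ""])
    return PhenotypeMatrix(df.iloc[:, 1:].to_numpy(dtype=float),
                           env_names=list(df.columns[1:]))


def read_architecture(path) -> QTLArchitecture:
    """Read a QTL architecture: chromosome, position_cM, effect_E1..effect_Ee."""
    df = pd.read_csv(path, sep="\t", comment="#")
    eff_cols = [c for c in df.columns if c.startswith("effect_")]
    if not eff_cols:
        raise ValueError(f"{path}: architecture file has no effect_E* columns")
    return QTLArchitecture(df["chromosome"].astype(str), df["position_cM"],
                           df[eff_cols].to_numpy(dtype=float))


def read_inputs(map_path, genotype_path, phenotype_path):
    """Read and cross-check the three standard inputs."""
    gmap = read_map(map_path)
    geno = read_genotypes(genotype_path, gmap)
    phen = read_phenotypes(phenotype_path)
    if geno.n_individuals != phen.n_individuals:
        raise ValueError("genotype and phenotype files disagree on individual count")
    return gmap, geno, phen


# ---------------------------------------------------------------------------
# writers


def _write_with_meta(path, df: pd.DataFrame, metadata: dict | None):
    buf = _io.StringIO()
    for k, v in (metadata or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=False, na_rep="NA")
    Path(path).write_text(buf.getvalue())


def write_map(path, gmap: GeneticMap, metadata: dict | None = None):
    _write_with_meta(path, gmap.table, metadata)


def write_genotypes(path, geno: MarkerGenotypes, metadata: dict | None = None,
                    dialect: str = "letters"):
    if dialect == "letters":
        mapped = np.where(np.isnan(geno.values), "-",
                          np.where(geno.values > 0, "A", "B"))
    else:
        mapped = np.where(np.isnan(geno.values), "-1",
                          np.where(geno.values > 0, "2", "0"))
    df = pd.DataFrame(mapped, columns=geno.marker_names)
    df.insert(0, "individual", [f"I{i + 1}" for i in range(geno.n_individuals)])
    _write_with_meta(path, df, metadata)


def write_phenotypes(path, phen: PhenotypeMatrix, metadata: dict | None = None):
    df = pd.DataFrame(phen.values, columns=phen.env_names)
    df.insert(0, "individual", [f"I{i + 1}" for i in range(phen.n_individuals)])
    _write_with_meta(path, df, metadata)


def write_architecture(path, arch: QTLArchitecture, metadata: dict | None = None):
    _write_with_meta(path, arch.to_frame(), metadata)


def write_table(path, df: pd.DataFrame, metadata: dict | None = None):
    """Write any result table (scan profile, power report) with metadata header."""
    _write_with_meta(path, df, metadata)
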