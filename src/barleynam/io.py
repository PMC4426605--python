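"""TSV dialects shared by all pipeline stages.

Everything is UTF-8 tab-separated text with a header row; missing values are
written as ``NA``. Files written by the pipeline start with a provenance
comment line (tool version, master seed, config hash) which readers skip.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from . import __version__
from .genmap import GeneticMap

NA = "NA"


def provenance_line(seed=None, config_hash=None) -> str:
    parts = [f"barleynam v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return "# " + " ".join(parts)


def config_hash(config: dict) -> str:
    return hashlib.sha256(repr(sorted(config.items())).encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, seed=None, config_hash=None, index=False):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, config_hash) + "\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA], **kwargs)


def write_genotypes(geno: pd.DataFrame, path, **prov):
    write_tsv(geno.reset_index(), path, **prov)


def read_genotypes(path) -> pd.DataFrame:
    return read_tsv(path).set_index("line_id")


def write_map(gmap: GeneticMap, path, **prov):
    write_tsv(gmap.to_frame(), path, **prov)


def read_map(path) -> GeneticMap:
    return GeneticMap(read_tsv(path))


def write_series(series: pd.Series, path, **prov):
    write_tsv(series.rename_axis("line_id").reset_index(), path, **prov)


def read_series(path, column) -> pd.Series:
    df = read_tsv(path).set_index("line_id")
    return df[column]
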