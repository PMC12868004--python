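"""Domain types and tabular I/O shared by every stage of the pipeline.

The pipeline operates on a wide protein-abundance table (proteins x samples,
linear intensities, missing values allowed) paired with a sample annotation
table mapping each sample to a donor and one of thirteen gross neuroanatomical
regions.  An optional gene x region nTPM table and a protein-to-gene
identifier map feed the cross-omics comparison.

All on-disk formats are tab-separated UTF-8 with a header row.  Missing
values are encoded as an empty cell or the literal ``NA``, nothing else.
Protein and gene identifiers are case-sensitive.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "REGIONS",
    "CORTICAL_LOBES",
    "FormatError",
    "ValidationError",
    "parse_region",
    "SampleAnnotation",
    "AbundanceMatrix",
    "RnaTable",
    "AnalysisConfig",
    "read_abundance_matrix",
    "read_sample_annotations",
    "read_rna_table",
    "read_id_map",
    "annotations_to_frame",
    "write_results",
]


class FormatError(ValueError):
    """A file violates the expected tabular format."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class Region(str, Enum):
    """The thirteen gross neuroanatomical divisions of the study design.

    Declaration order is the canonical region order used for tie-breaking
    throughout the pipeline.  ``THA/HT`` and ``OB/OT`` appear in the
    anatomical literature with a slash; parsing accepts those aliases and
    maps them onto filesystem/column-safe tokens.
    """

    FL = "FL"  # frontal lobe
    TL = "TL"  # temporal lobe
    PL = "PL"  # parietal lobe
    OL = "OL"  # occipital lobe
    CB = "CB"  # cerebellum
    BS = "BS"  # brainstem
    THA_HT = "THA_HT"  # thalamus/hypothalamus
    OC = "OC"  # optic chiasm
    CC = "CC"  # corpus callosum
    VT = "VT"  # ventricles
    HIP = "HIP"  # hippocampus
    AN = "AN"  # amygdaloid nucleus
    OB_OT = "OB_OT"  # olfactory bulb/olfactory tract

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


REGIONS: tuple[Region, ...] = tuple(Region)

#: The four cerebral lobes (the cortical integration module).
CORTICAL_LOBES: tuple[Region, ...] = (Region.FL, Region.TL, Region.PL, Region.OL)

_SLASH_ALIASES = {"THA/HT": Region.THA_HT, "OB/OT": Region.OB_OT}
_TOKEN_TO_SLASH = {Region.THA_HT: "THA/HT", Region.OB_OT: "OB/OT"}


def parse_region(text: str) -> Region:
    """Parse a region code, accepting the slash aliases THA/HT and OB/OT."""
    token = str(text).strip()
    if token in _SLASH_ALIASES:
        return _SLASH_ALIASES[token]
    try:
        return Region(token)
    except ValueError:
        admissible = ", ".join(r.value for r in REGIONS)
        raise ValidationError(
            f"unknown region {token!r}; admissible codes: {admissible} "
            f"(slash forms THA/HT and OB/OT are accepted)"
        ) from None


def region_slash_label(region: Region) -> str:
    """The conventional anatomical label (slash form where applicable)."""
    return _TOKEN_TO_SLASH.get(region, region.value)


class SampleAnnotation(NamedTuple):
    sample_id: str
    donor_id: str
    region: Region


def annotations_to_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Annotation list as a DataFrame indexed by sample_id."""
    frame = pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "donor_id": [a.donor_id for a in annotations],
            "region": [a.region.value for a in annotations],
        }
    )
    return frame.set_index("sample_id", drop=False)


_STAGES = ("raw", "ppm", "log2ppm")


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance values with an explicit processing stage.

    ``values`` is a float DataFrame (index = protein ids, columns = sample
    ids) with NaN marking missing observations.  ``stage`` records what the
    numbers mean: ``raw`` linear intensities, ``ppm`` parts-per-million of
    the per-sample observed total, or ``log2ppm`` after log2 transform.
    Raw and ppm stages require all present values to be strictly positive
    (zero intensities denote non-detection and are coerced to missing at
    read time).
    """

    values: pd.DataFrame
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        self.values = self.values.astype(float)
        if self.stage in ("raw", "ppm"):
            arr = self.values.to_numpy()
            bad = np.asarray((arr <= 0) & ~np.isnan(arr))
            if bad.any():
                p, s = np.argwhere(bad)[0]
                raise ValidationError(
                    f"stage {self.stage!r} requires positive present values; "
                    f"found {arr[p, s]} at protein {self.values.index[p]!r}, "
                    f"sample {self.values.columns[s]!r}"
                )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean())


@dataclass
class RnaTable:
    """Gene x region nTPM table (consensus RNA abundance per region).

    Region labels follow the RNA-side vocabulary (e.g. Cx, CB, BS, HIP,
    THA_HT), which is coarser than the proteomic one.  nTPM values are
    nonnegative; NaN marks a missing measurement.
    """

    ntpm: pd.DataFrame

    def __post_init__(self) -> None:
        if self.ntpm.index.has_duplicates:
            raise FormatError("duplicate gene ids in RNA table")
        if self.ntpm.columns.has_duplicates:
            raise FormatError("duplicate region labels in RNA table")
        arr = self.ntpm.to_numpy(dtype=float)
        if np.any((arr < 0) & ~np.isnan(arr)):
            raise ValidationError("negative nTPM values are not allowed")
        self.ntpm = self.ntpm.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ntpm.index)

    @property
    def region_labels(self) -> list[str]:
        return list(self.ntpm.columns)


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable thresholds of the analysis, with the study's defaults.

    fc_threshold : linear fold-change ratio a region-specific protein must
        reach against the pooled remaining regions (default 1.5).
    alpha : BH-adjusted p-value cutoff (default 0.01).
    min_obs_max_region : minimum observations in the top region for a call.
    min_testable_regions : minimum regions with >=1 observation for the
        blocked ANOVA to be attempted.
    blocking : "blocked" whitens donor blocks with the consensus intra-donor
        correlation before the one-way ANOVA; "oneway" skips blocking.
    trim : tail fraction trimmed from the Fisher-z per-protein correlations
        before averaging into the consensus.
    rho_clamp : clamp interval for per-protein correlation estimates.
    rna_lower : nTPM floor; values below it are treated as missing.
    rna_ratio : log2-scale ratio for the RNA region-specificity rule.
    fc_scale : "log2" (geometric-mean ratio, default) or "linear" region
        means for the fold change.
    quartile_bounds : cumulative-abundance cut points, ending at 1.0.
    """

    fc_threshold: float = 1.5
    alpha: float = 0.01
    min_obs_max_region: int = 2
    min_testable_regions: int = 3
    blocking: str = "blocked"
    trim: float = 0.15
    rho_clamp: tuple[float, float] = (-0.95, 0.95)
    rna_lower: float = 1.0
    rna_ratio: float = 2.0
    distance: str = "pearson"
    linkage: str = "complete"
    quartile_bounds: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
    fc_scale: str = "log2"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fc_threshold > 0:
            raise ValidationError("fc_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 <= self.trim < 0.5:
            raise ValidationError("trim must lie in [0, 0.5)")
        if self.blocking not in ("blocked", "oneway"):
            raise ValidationError("blocking must be 'blocked' or 'oneway'")
        if self.distance != "pearson":
            raise ValidationError("only Pearson correlation distance is supported")
        if self.linkage != "complete":
            raise ValidationError("only complete linkage is supported")
        if self.fc_scale not in ("log2", "linear"):
            raise ValidationError("fc_scale must be 'log2' or 'linear'")
        bounds = tuple(float(b) for b in self.quartile_bounds)
        if len(bounds) < 1 or bounds[-1] != 1.0:
            raise ValidationError("quartile_bounds must end at 1.0")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])) or bounds[0] <= 0:
            raise ValidationError("quartile_bounds must be strictly increasing and positive")
        lo, hi = self.rho_clamp
        if not -1 < lo < hi < 1:
            raise ValidationError("rho_clamp must be an interval inside (-1, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("rho_clamp", "quartile_bounds"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["rho_clamp"] = list(out["rho_clamp"])
        out["quartile_bounds"] = list(out["quartile_bounds"])
        return out

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers


def _check_unique_header(path: Path) -> list[str]:
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise FormatError(f"{path}: duplicate column {name!r} in header")
        seen.add(name)
    return header


def read_abundance_matrix(path: str | Path, stage: str = "raw") -> AbundanceMatrix:
    """Read a wide protein x sample abundance TSV.

    First column must be ``protein_id``; empty cells and ``NA`` are missing.
    In a raw matrix, zeros denote below-detection signals and are coerced to
    missing (logged), preventing -inf under the later log2 transform.
    """
    path = Path(path)
    header = _check_unique_header(path)
    if not header or header[0] != "protein_id":
        raise FormatError(f"{path}: first column must be 'protein_id', got {header[:1]}")
    raw = pd.read_csv(
        path, sep="\t", dtype=str, na_values=["", "NA"], keep_default_na=False
    )
    if raw["protein_id"].duplicated().any():
        dupes = raw.loc[raw["protein_id"].duplicated(), "protein_id"].unique().tolist()
        raise FormatError(f"{path}: duplicate protein ids: {dupes}")
    table = raw.set_index("protein_id")
    numeric = table.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & table.notna()
    if bad.to_numpy().any():
        p, s = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {table.iat[p, s]!r} at row "
            f"{table.index[p]!r}, column {table.columns[s]!r}"
        )
    if stage == "raw":
        zeros = (numeric == 0).to_numpy().sum()
        if zeros:
            logger.info("%s: coerced %d zero intensities to missing", path, int(zeros))
            numeric = numeric.mask(numeric == 0)
    return AbundanceMatrix(values=numeric, stage=stage)


def read_sample_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the sample annotation TSV (sample_id, donor_id, region)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "donor_id", "region"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if table["sample_id"].duplicated().any():
        dupes = table.loc[table["sample_id"].duplicated(), "sample_id"].unique().tolist()
        raise FormatError(f"{path}: duplicate sample ids: {dupes}")
    return [
        SampleAnnotation(row.sample_id, row.donor_id, parse_region(row.region))
        for row in table.itertuples()
    ]


def read_rna_table(path: str | Path) -> RnaTable:
    """Read a gene x region nTPM TSV (first column ``gene_id``)."""
    path = Path(path)
    header = _check_unique_header(path)
    if not header or header[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {header[:1]}")
    table = pd.read_csv(
        path, sep="\t", na_values=["", "NA"], keep_default_na=False, index_col="gene_id"
    )
    return RnaTable(ntpm=table.astype(float))


def read_id_map(path: str | Path) -> pd.DataFrame:
    """Read the protein-to-gene identifier map (protein_id, gene_id)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "gene_id"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if table["protein_id"].duplicated().any():
        dupes = table.loc[table["protein_id"].duplicated(), "protein_id"].unique().tolist()
        raise FormatError(f"{path}: protein mapped to more than one gene: {dupes}")
    return table[["protein_id", "gene_id"]]


# ---------------------------------------------------------------------------
# writers

_FLOAT_FORMAT = "%.12g"  # 12 significant digits: round-trips analysis output


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, na_rep="NA", float_format=_FLOAT_FORMAT)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    manifest_name: str = "run_manifest.txt",
    extra_lines: Iterable[str] = (),
) -> list[Path]:
    """Write named result tables as TSVs plus a run manifest.

    Each table becomes ``<name>.tsv`` with a stable column order (as given).
    The manifest lists every file with its content hash, the config hash and
    the seed, so reruns are auditable; byte-identical inputs and seed yield
    byte-identical tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        write_table(table, path)
        written.append(path)
    manifest = out_dir / manifest_name
    with open(manifest, "w", encoding="utf-8") as handle:
        handle.write(f"config_hash\t{config.content_hash() if config else 'NA'}\n")
        handle.write(f"seed\t{seed if seed is not None else 'NA'}\n")
        for line in extra_lines:
            handle.write(line.rstrip("\n") + "\n")
        for path in written:
            handle.write(f"file\t{path.name}\t{_sha256(path)}\n")
    written.append(manifest)
    return written
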