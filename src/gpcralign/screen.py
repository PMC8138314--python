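"""All-vs-all screening of complexes and repurposing-hit reporting.

Every ordered (target, reference) pair gets a normalized score N = T/R; the
matrix is directed because R is the reference's self-alignment score.  Pairs
with N at or above the threshold (0.5 by default, the screening rule used
with this method) and distinct ids are reported as hits, sorted by
descending N with ties broken by target then reference id.  Profiles and
self-scores are computed once per complex, so a screen of k complexes does
exactly k self-alignments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .aligner import SCOPES, align_complexes, self_score
from .errors import GpcrAlignError, ParseError, ValidationError
from .matrices import ScoringParams, build_model
from .profiler import ComplexProfile, build_profile, get_scheme
from .structio import BindingSiteSpec, find_binding_site, load_complex
from .topology import detect_helices, load_annotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """One screening configuration: scheme, scoring, threshold, scope."""

    scheme: str = "8DP"
    scoring: ScoringParams = field(default_factory=ScoringParams)
    threshold: float = 0.5
    scope: str = "pocket"
    cutoff: float = 4.0
    custom_matrix_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold:
            raise ValidationError(f"threshold must be > 0, got {self.threshold}")
        if self.scope not in SCOPES:
            raise ValidationError(f"unknown scope {self.scope!r}")
        get_scheme(self.scheme)  # validates the name


@dataclass(frozen=True)
class ScreenEntry:
    """One manifest row: where a complex lives and how to interpret it."""

    id: str
    path: str
    ligand_code: str | None = None
    receptor_label: str | None = None
    annotation_path: str | None = None


@dataclass
class ScreenTable:
    """Directed normalized-score matrix plus the thresholded hit list."""

    ids: list[str]
    n_matrix: np.ndarray  # rows = target, columns = reference
    hits: list[tuple[str, str, float]]
    config: ScreenConfig
    receptor_labels: dict[str, str]
    skipped: list[str] = field(default_factory=list)


def read_manifest(path: str | Path) -> list[ScreenEntry]:
    """Parse a TSV manifest: ``id path ligand_code receptor_label
    annotation_path`` ('-' marks an absent optional field)."""
    entries = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ParseError(
                f"{path}:{lineno}: expected 'id path [ligand] [label] "
                f"[annotation]', got {len(parts)} fields"
            )
        parts += ["-"] * (5 - len(parts))
        ident, cpath, ligand, label, annotation = parts[:5]

        def opt(value: str) -> str | None:
            return None if value in ("-", "") else value

        entries.append(
            ScreenEntry(
                id=ident,
                path=cpath,
                ligand_code=opt(ligand),
                receptor_label=opt(label),
                annotation_path=opt(annotation),
            )
        )
    return entries


def _profile_entry(entry: ScreenEntry, config: ScreenConfig) -> ComplexProfile:
    cx = load_complex(entry.path, ligand_code=entry.ligand_code)
    if entry.annotation_path:
        annotation = load_annotation(entry.annotation_path, cx)
    else:
        annotation = detect_helices(cx)
    pocket = find_binding_site(cx, BindingSiteSpec(cutoff=config.cutoff))
    profile = build_profile(cx, annotation, pocket, get_scheme(config.scheme))
    return replace(profile, source_id=entry.id)


def run_screen(
    entries: list[ScreenEntry],
    configs: ScreenConfig | list[ScreenConfig],
) -> list[ScreenTable]:
    """Screen all ordered pairs under each configuration.

    Complexes that fail to load or profile are logged and skipped; fewer
    than two usable complexes is an error.
    """
    single = isinstance(configs, ScreenConfig)
    config_list = [configs] if single else list(configs)
    tables = []
    for config in config_list:
        model = build_model(
            get_scheme(config.scheme),
            config.scoring,
            custom_path=config.custom_matrix_path,
        )
        profiles: dict[str, ComplexProfile] = {}
        skipped: list[str] = []
        for entry in entries:
            try:
                profiles[entry.id] = _profile_entry(entry, config)
            except (GpcrAlignError, OSError) as exc:
                logger.warning("skipping %s: %s", entry.id, exc)
                skipped.append(entry.id)
        if len(profiles) < 2:
            raise ValidationError(
                f"need >= 2 usable complexes, have {len(profiles)} "
                f"(skipped: {skipped})"
            )
        ids = [e.id for e in entries if e.id in profiles]
        self_scores = {
            ident: self_score(profiles[ident], model, scope=config.scope)
            for ident in ids
        }
        k = len(ids)
        n_matrix = np.ones((k, k), dtype=float)
        for i, target in enumerate(ids):
            for j, reference in enumerate(ids):
                if i == j:
                    continue  # N(self) = 1 by definition of the normalization
                summary = align_complexes(
                    profiles[target],
                    profiles[reference],
                    model,
                    scope=config.scope,
                    reference_self=self_scores[reference],
                )
                n_matrix[i, j] = summary.normalized
        hits = [
            (ids[i], ids[j], float(n_matrix[i, j]))
            for i in range(k)
            for j in range(k)
            if i != j and n_matrix[i, j] >= config.threshold
        ]
        hits.sort(key=lambda h: (-h[2], h[0], h[1]))
        labels = {
            e.id: (e.receptor_label or e.id) for e in entries if e.id in profiles
        }
        tables.append(
            ScreenTable(
                ids=ids,
                n_matrix=n_matrix,
                hits=hits,
                config=config,
                receptor_labels=labels,
                skipped=skipped,
            )
        )
    return tables


def partition_hits(
    table: ScreenTable, receptor_labels: dict[str, str] | None = None
) -> tuple[list[tuple[str, str, float]], list[tuple[str, str, float]], float]:
    """Split hits into same-receptor and cross-receptor lists.

    Returns (same, cross, cross_fraction); cross-receptor hits are the
    repurposing candidates.
    """
    labels = receptor_labels if receptor_labels is not None else table.receptor_labels
    missing = {t for t, r, _ in table.hits for t in (t, r)} - set(labels)
    if missing:
        raise ValidationError(f"missing receptor labels for {sorted(missing)}")
    same = [h for h in table.hits if labels[h[0]] == labels[h[1]]]
    cross = [h for h in table.hits if labels[h[0]] != labels[h[1]]]
    fraction = len(cross) / len(table.hits) if table.hits else 0.0
    return same, cross, fraction


def write_screen_outputs(table: ScreenTable, out_dir: str | Path) -> None:
    """Write the score matrix TSV, hits TSV and run-metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "n_matrix.tsv", "w") as fh:
        fh.write("target\\reference\t" + "\t".join(table.ids) + "\n")
        for i, ident in enumerate(table.ids):
            row = "\t".join(f"{v:.6f}" for v in table.n_matrix[i])
            fh.write(f"{ident}\t{row}\n")
    with open(out / "hits.tsv", "w") as fh:
        fh.write("target\treference\tN\n")
        for target, reference, value in table.hits:
            fh.write(f"{target}\t{reference}\t{value:.6f}\n")
    config = table.config
    metadata = {
        "tool": "gpcralign",
        "version": __version__,
        "scheme": config.scheme,
        "scoring": {
            "mode": config.scoring.mode,
            "miss": config.scoring.miss,
            "gap": config.scoring.gap,
            "flag_policy": config.scoring.flag_policy,
            "aggregation": config.scoring.aggregation,
            "gpcrtm_is_synthetic_standin": config.scoring.mode == "gpcrtm",
        },
        "threshold": config.threshold,
        "scope": config.scope,
        "cutoff": config.cutoff,
        "ids": table.ids,
        "skipped": table.skipped,
        "deterministic": True,
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")
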