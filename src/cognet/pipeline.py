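"""Full-analysis orchestration: config, stage composition, artifact bundle.

``run_pipeline`` turns one wordlist into the complete set of analysis
artifacts -- character matrix, distances, NeighborNet, bootstrap tree
samples, consensus networks, group-support table, per-concept change counts
-- for the full taxon set and for each configured period preset, plus a
manifest recording every parameter and derived seed.  Identical config and
seed produce byte-identical non-log outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .analysis import (
    PERIOD_PRESETS,
    GroupDefinition,
    filter_by_period,
    group_support_table,
    min_changes_per_concept,
    read_groups,
    support_table_tsv,
)
from .bootstrap import bootstrap_trees, consensus_network
from .coding import to_binary_matrix, write_nexus_characters
from .distance import hamming_distances, write_phylip
from .errors import CognetError, EmptySelectionError, ValidationError
from .inference import distance_tree
from .nnet import neighbor_net
from .splits import write_splits_nexus
from .tree import write_tree_sample
from .util import derive_seed
from .wordlist import Wordlist, read_wordlist

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the CLI flags.

    ``columns`` remaps wordlist header names; ``periods`` names presets from
    :data:`cognet.analysis.PERIOD_PRESETS`; ``groups_path`` points at a
    plain-text group config (``name: taxon, taxon`` per line).
    """

    input_path: str
    output_dir: str
    columns: Optional[dict] = None
    missing_policy: str = "zero"
    normalize: bool = True
    methods: Sequence[str] = ("nj", "bionj", "mp")
    n_reps: int = 1000
    seed: int = 1
    cutoff: float = 0.15
    periods: Sequence[str] = ()
    groups_path: Optional[str] = None
    charmap: bool = True

    def validate(self) -> None:
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if not (0.0 < self.cutoff <= 1.0):
            raise ValidationError("cutoff must be in (0, 1]")
        if self.missing_policy not in ("zero", "missing"):
            raise ValidationError(f"unknown missing policy {self.missing_policy!r}")
        for m in self.methods:
            if m not in ("nj", "bionj", "mp"):
                raise ValidationError(f"unknown method {m!r}")
        for p in self.periods:
            if p not in PERIOD_PRESETS:
                raise ValidationError(
                    f"unknown period preset {p!r}; known: {sorted(PERIOD_PRESETS)}"
                )
        if not Path(self.input_path).exists():
            raise ValidationError(f"input not found: {self.input_path}")
        if self.groups_path and not Path(self.groups_path).exists():
            raise ValidationError(f"groups file not found: {self.groups_path}")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Read a flat ``key = value`` config file (lists comma-separated)."""
        raw: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"malformed config line: {line!r}")
            k, v = line.split("=", 1)
            raw[k.strip()] = v.strip()
        kw: dict = {}
        str_keys = {
            "input_path", "output_dir", "missing_policy", "groups_path",
        }
        for k in str_keys & raw.keys():
            kw[k] = raw[k]
        if "methods" in raw:
            kw["methods"] = tuple(x.strip() for x in raw["methods"].split(",") if x.strip())
        if "periods" in raw:
            kw["periods"] = tuple(x.strip() for x in raw["periods"].split(",") if x.strip())
        for k, conv in (("n_reps", int), ("seed", int), ("cutoff", float)):
            if k in raw:
                kw[k] = conv(raw[k])
        for k in ("normalize", "charmap"):
            if k in raw:
                kw[k] = raw[k].lower() in ("1", "true", "yes")
        if "input_path" not in kw or "output_dir" not in kw:
            raise ValidationError("config must set input_path and output_dir")
        return cls(**kw)


def _run_scope(
    name: str,
    wl: Wordlist,
    cfg: PipelineConfig,
    groups: list[GroupDefinition],
    outdir: Path,
    manifest: dict,
) -> None:
    scope_dir = outdir / name
    scope_dir.mkdir(parents=True, exist_ok=True)
    info: dict = {"taxa": len(wl.taxa), "entries": len(wl)}
    manifest["scopes"][name] = info

    m = to_binary_matrix(wl, missing_policy=cfg.missing_policy)
    info["characters"] = m.n_characters
    (scope_dir / "characters.nex").write_text(write_nexus_characters(m), encoding="utf-8")

    if m.n_taxa < 2:
        info["note"] = "fewer than 2 taxa; distances and networks skipped"
        return
    dm = hamming_distances(m, normalize=cfg.normalize)
    (scope_dir / "distances.phy").write_text(write_phylip(dm), encoding="utf-8")

    nnet = neighbor_net(dm)
    (scope_dir / "nnet.nex").write_text(write_splits_nexus(nnet), encoding="utf-8")

    min_taxa = {"nj": 3, "bionj": 3, "mp": 4}
    for method in cfg.methods:
        if m.n_taxa < min_taxa[method]:
            info[f"bootstrap_{method}"] = "skipped: too few taxa"
            continue
        seed = derive_seed(cfg.seed, f"{name}:bs:{method}")
        sample = bootstrap_trees(m, method, n_reps=cfg.n_reps, seed=seed)
        info[f"bootstrap_{method}"] = {
            "seed": seed, "n_reps": sample.n_reps, "n_skipped": sample.n_skipped,
        }
        (scope_dir / f"bootstrap_{method}.nwk").write_text(
            write_tree_sample(sample.trees), encoding="utf-8"
        )
        cnet = consensus_network(sample, cutoff=cfg.cutoff)
        (scope_dir / f"cnet_{method}.nex").write_text(
            write_splits_nexus(cnet), encoding="utf-8"
        )

    if groups:
        usable = [g for g in groups if g.members <= set(m.taxa) and len(g.members) >= 2
                  and len(g.members) < m.n_taxa]
        if usable:
            table = group_support_table(
                m, usable, methods=tuple(cfg.methods), n_reps=cfg.n_reps,
                seed=derive_seed(cfg.seed, f"{name}:support"),
            )
            (scope_dir / "group_support.tsv").write_text(
                support_table_tsv(table), encoding="utf-8"
            )
        info["groups_scored"] = len(usable)

    if cfg.charmap and m.n_taxa >= 3:
        ref = distance_tree(m, method="nj", normalize=cfg.normalize)
        lines = ["CONCEPT\tMIN_CHANGES\tN_STATES"]
        for c in wl.concepts:
            states = {e.cogid for e in wl.entries if e.concept == c}
            lines.append(f"{c}\t{min_changes_per_concept(wl, c, ref)}\t{len(states)}")
        (scope_dir / "charmap_nj.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Scope ``full`` always runs; each configured period preset adds a scope.
    A preset admitting no taxa is recorded in the manifest and skipped.  Any
    other stage failure aborts the run with a ``FAILED`` marker file naming
    the stage (partial outputs are retained).
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    wl = read_wordlist(cfg.input_path, columns=cfg.columns)
    groups = (
        read_groups(Path(cfg.groups_path).read_text(encoding="utf-8"))
        if cfg.groups_path
        else []
    )
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "missing_policy": cfg.missing_policy,
            "normalize": cfg.normalize,
            "methods": list(cfg.methods),
            "n_reps": cfg.n_reps,
            "cutoff": cfg.cutoff,
            "periods": list(cfg.periods),
        },
        "input": str(cfg.input_path),
        "scopes": {},
    }
    stage = "full"
    try:
        _run_scope("full", wl, cfg, groups, outdir, manifest)
        for preset in cfg.periods:
            stage = preset
            try:
                sub = filter_by_period(wl, PERIOD_PRESETS[preset])
            except EmptySelectionError:
                manifest["scopes"][preset] = {"note": "skipped: empty selection"}
                logger.warning("period %s admits no taxa; skipped", preset)
                continue
            _run_scope(preset, sub, cfg, groups, outdir, manifest)
    except CognetError as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        raise
    finally:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return outdir


__all__ = ["PipelineConfig", "run_pipeline"]
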