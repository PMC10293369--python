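"""End-to-end orchestration: inputs → statistics → genealogy → delimitation.

``run_pipeline`` executes every stage over one alignment/tree/metadata bundle
and writes a reproducible report directory:

* ``haplotypes.tsv`` — the haplotype partition;
* ``group_stats.tsv`` / ``group_stats.json`` — per-group n, L_eff, S, k̄, π,
  Tajima's D, R2 and raggedness (4 decimals in the TSV, full precision in the
  JSON sidecar);
* ``mismatch_<group>.tsv`` — observed (and expected) mismatch spectra;
* ``genealogy.dot`` / ``genealogy.json`` — the haplotype genealogy;
* ``diagnostics.tsv`` / ``substitution_map.json`` — barcoding diagnostics and
  the full substitution ledger;
* ``delimitation.tsv`` and ``summary.md`` — WP verdicts, consensus decisions
  and the valid-species summary;
* ``MANIFEST.json`` — input hashes, configuration, seed and tool version.

Groups for the demographic statistics are every named clade plus every
species label with at least two sequences, plus the whole in-group
(``ALL``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .cbb import diagnose_all, fitch_optimize
from .haplotypes import build_genealogy, collapse_haplotypes, export_genealogy
from .io import (
    Alignment,
    PhyloTree,
    SampleTable,
    map_positions,
    read_alignment,
    read_samples,
    read_tree,
)
from .popgen import group_stats, mismatch_distribution
from .wp import consensus_delimit, summarize, wp_delimit

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_from_paths"]


@dataclass
class PipelineConfig:
    alignment: str
    tree: str
    samples: str
    out: str
    reference: Optional[str] = None
    support_threshold: float = 0.95
    site_policy: str = "complete-deletion"
    haplotype_policy: str = "strict"
    min_diagnostics: int = 1
    require_exclusive: bool = False
    mismatch_model: str = "constant"
    seed: int = 0
    allow_polytomies: bool = False

    def __post_init__(self):
        if not 0 < self.support_threshold <= 1:
            raise ValueError("support_threshold must lie in (0, 1]")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_group_stats(groups: list, outdir: Path) -> None:
    rows = [g.as_row() for g in groups]
    cols = list(rows[0])
    with open(outdir / "group_stats.tsv", "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    with open(outdir / "group_stats.json", "w") as fh:
        json.dump([dataclasses.asdict(g) for g in groups], fh, indent=2)


def _stat_groups(alignment: Alignment, samples: SampleTable) -> dict:
    groups: dict[str, list] = {}
    ingroup = samples.ingroup_ids()
    if len(ingroup) >= 2:
        groups["ALL"] = ingroup
    for clade in samples.clade_labels():
        groups.setdefault(clade, samples.tips_of_clade(clade))
    for label in samples.species_labels():
        groups.setdefault(label, samples.tips_of_species(label))
    return groups


def run_pipeline(
    alignment: Alignment,
    tree: PhyloTree,
    samples: SampleTable,
    config: PipelineConfig,
    reference: Optional[str] = None,
    input_hashes: Optional[dict] = None,
) -> dict:
    """Run every stage and write the report bundle to ``config.out``.

    Returns a dict with the in-memory results (haplotypes, genealogy,
    diagnostics report, WP verdicts, consensus decisions, summary).
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "haplodelim",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": input_hashes or {},
        "completed_stages": [],
    }

    def done(stage: str) -> None:
        manifest["completed_stages"].append(stage)
        with open(outdir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    missing = set(tree.leaf_names) ^ set(alignment.ids)
    if missing:
        raise ValueError(f"tree/alignment sample mismatch: {sorted(missing)[:5]}")
    for sid in alignment.ids:
        if sid not in samples:
            raise ValueError(f"sample {sid!r} missing from metadata table")

    posmap = None
    if reference is not None:
        posmap = map_positions(alignment, reference)
        done("position_map")

    haplotypes = collapse_haplotypes(alignment, policy=config.haplotype_policy)
    with open(outdir / "haplotypes.tsv", "w") as fh:
        fh.write("haplotype\tcount\tmembers\n")
        for h in haplotypes:
            fh.write(f"{h.name}\t{h.count}\t{','.join(h.members)}\n")
    done("haplotypes")

    stat_rows = []
    for name, ids in _stat_groups(alignment, samples).items():
        sub = alignment.subset(ids)
        st = group_stats(sub, site_policy=config.site_policy, name=name)
        stat_rows.append(st)
        if sub.n >= 2:
            mm = mismatch_distribution(
                sub,
                model=config.mismatch_model,
                site_policy=config.site_policy,
                seed=config.seed,
            )
            with open(outdir / f"mismatch_{name}.tsv", "w") as fh:
                fh.write("class\tcount\tobserved\texpected\n")
                for i, (c, x) in enumerate(zip(mm.counts, mm.observed)):
                    e = "" if mm.expected is None else f"{mm.expected[i]:.6f}"
                    fh.write(f"{i}\t{c}\t{x:.6f}\t{e}\n")
    _write_group_stats(stat_rows, outdir)
    done("group_stats")

    genealogy = build_genealogy(tree, alignment, haplotypes)
    (outdir / "genealogy.dot").write_text(
        export_genealogy(genealogy, "dot", samples=samples)
    )
    (outdir / "genealogy.json").write_text(export_genealogy(genealogy, "json"))
    done("genealogy")

    submap = fitch_optimize(tree, alignment)
    with open(outdir / "substitution_map.json", "w") as fh:
        json.dump(
            {
                "total_score": submap.total_score,
                "events": [dataclasses.asdict(ev) for ev in submap.events],
            },
            fh,
            indent=2,
        )
    cbb_report = diagnose_all(
        tree,
        alignment,
        samples,
        position_map=posmap,
        min_diagnostics=config.min_diagnostics,
        require_exclusive=config.require_exclusive,
        submap=submap,
    )
    with open(outdir / "diagnostics.tsv", "w") as fh:
        fh.write(
            "clade\tsite\tposition\tfrom\tto\texclusivity\tretained\n"
        )
        for name, entry in cbb_report.items():
            if not entry["applicable"]:
                fh.write(f"{name}\tNA\tNA\tNA\tNA\tnon-exclusive\tNA\n")
                continue
            for d in entry["set"].diagnostics:
                fh.write(
                    f"{name}\t{d.site}\t{d.position_label}\t{d.from_state}\t"
                    f"{d.to_state}\t{d.exclusivity}\t"
                    f"{'yes' if d.retained_by_all_members else 'no'}\n"
                )
    done("cbb_diagnostics")

    verdicts = wp_delimit(
        tree, samples, haplotypes, support_threshold=config.support_threshold
    )
    decisions = consensus_delimit(verdicts, cbb_report)
    summary = summarize(decisions)
    with open(outdir / "delimitation.tsv", "w") as fh:
        fh.write(
            "label\texclusivity\town_support\tsister_support\twp_decision\t"
            "cbb_total\tcbb_exclusive\tfinal\tlump_partners\n"
        )
        for d in decisions:
            v = d.wp
            own = "" if v.own_support is None else f"{v.own_support:.2f}"
            sis = "" if v.sister_support is None else f"{v.sister_support:.2f}"
            fh.write(
                f"{d.species_label}\t{v.exclusivity}\t{own}\t{sis}\t"
                f"{v.decision}\t{d.cbb_total}\t{d.cbb_exclusive}\t{d.final}\t"
                f"{','.join(v.lump_partners)}\n"
            )
    done("wp_consensus")

    lines = [
        "# Species delimitation summary",
        "",
        f"- samples: {alignment.n}; alignment length: {alignment.length}",
        f"- haplotypes: {len(haplotypes)}",
        f"- parsimony score on the fixed tree: {submap.total_score}",
        f"- support threshold: > {config.support_threshold}",
        "",
        f"**Valid in-group species ({summary['n_valid_species']}):** "
        + (", ".join(summary["valid_species"]) or "none"),
        "",
        f"**Possible junior synonyms ({summary['n_synonym_candidates']}):**",
    ]
    for d in decisions:
        if d.final.startswith("possible-junior-synonym"):
            lines.append(f"- {d.species_label}: {d.final}")
    lines += ["", "## Per-clade diagnostics", ""]
    for name, entry in cbb_report.items():
        if entry["applicable"]:
            s = entry["set"]
            lines.append(
                f"- {name}: {s.n_total} diagnostics "
                f"({s.n_global} globally exclusive, {s.n_ingroup} in-group "
                f"exclusive), {s.n_retained} retained"
            )
        else:
            lines.append(f"- {name}: CBB not applicable (non-exclusive)")
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    done("summary")

    return {
        "haplotypes": haplotypes,
        "genealogy": genealogy,
        "group_stats": stat_rows,
        "substitution_map": submap,
        "cbb_report": cbb_report,
        "wp_verdicts": verdicts,
        "decisions": decisions,
        "summary": summary,
    }


def run_pipeline_from_paths(config: PipelineConfig) -> dict:
    """Read the inputs named in ``config`` and run the pipeline."""
    alignment = read_alignment(config.alignment)
    tree = read_tree(config.tree, allow_polytomies=config.allow_polytomies)
    samples = read_samples(config.samples)
    reference = None
    hashes = {
        "alignment": _sha256(config.alignment),
        "tree": _sha256(config.tree),
        "samples": _sha256(config.samples),
    }
    if config.reference:
        ref_aln = read_alignment(config.reference)
        reference = next(iter(dict(ref_aln.items()).values()))
        hashes["reference"] = _sha256(config.reference)
    return run_pipeline(
        alignment, tree, samples, config, reference=reference, input_hashes=hashes
    )
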