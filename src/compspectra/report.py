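"""One-shot report runs: a YAML config in, a reproducible report bundle out.

The bundle contains the requested TSV/JSON tables plus a run manifest
recording input hashes, all decision flags, the seed and the tool version,
so every numeric cell can be reproduced from the manifest alone.

Pipeline order: masking is applied first (codon positions and charsets are
defined on original coordinates), then RY recoding; spectra and
compositional statistics are computed on the resulting matrix. Codon usage
is always tabulated on the unmasked, unrecoded matrix, since it needs the
original reading frames.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .alignment import Alignment, read_alignment
from .composition import class_deviations, codon_usage, rcfv, rcv, skews
from .errors import CompspectraError
from .partitions import PartitionScheme, TaxonGroups, read_charsets_nexus, read_charsets_tsv
from .recoding import mask_columns, recode_ry
from .spectrum import filter_focal, label_hypotheses, spectrum, spectrum_frame


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_charsets(path) -> PartitionScheme:
    path = Path(path)
    if path.suffix.lower() in (".nex", ".nexus", ".nxs"):
        return read_charsets_nexus(path)
    return read_charsets_tsv(path)


def run_report(config, out_dir: Optional[str] = None) -> dict:
    """Execute a configured analysis run and write the report bundle.

    ``config`` is a YAML path or an equivalent dict. Returns the manifest
    (also written as ``manifest.json``).
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        cfg = yaml.safe_load(config_path.read_text())
        inputs = {str(config_path): _sha256(config_path)}
    else:
        cfg = dict(config)
        inputs = {}
    if not isinstance(cfg, dict) or "alignment" not in cfg:
        raise CompspectraError("config must name an 'alignment'")

    aln_path = Path(cfg["alignment"])
    if not aln_path.exists():
        raise CompspectraError(f"alignment not found: {aln_path}")
    out = Path(out_dir or cfg.get("out", "report"))
    out.mkdir(parents=True, exist_ok=True)
    inputs[str(aln_path)] = _sha256(aln_path)
    aln = read_alignment(
        aln_path, cfg.get("format", "auto"), cfg.get("alphabet", "dna")
    )

    scheme = None
    if cfg.get("charsets"):
        cs_path = Path(cfg["charsets"])
        if not cs_path.exists():
            raise CompspectraError(f"charsets not found: {cs_path}")
        inputs[str(cs_path)] = _sha256(cs_path)
        scheme = read_charsets(cs_path)
        frames = cfg.get("frames") or {}
        scheme.frames.update({str(k): int(v) for k, v in frames.items()})

    groups = None
    if cfg.get("groups"):
        g_path = Path(cfg["groups"])
        if not g_path.exists():
            raise CompspectraError(f"groups not found: {g_path}")
        inputs[str(g_path)] = _sha256(g_path)
        groups = TaxonGroups.from_yaml(g_path)
        groups.validate(aln.taxa)

    analyses = list(cfg.get("analyses", ["rcfv", "skew"]))
    results: dict = {}
    outputs: dict[str, str] = {}

    def write_frame(frame, name: str) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", float_format="%.12g")
        outputs[name] = _sha256(path)

    # codon usage runs on the original matrix (needs original frames)
    if "codon_usage" in analyses:
        if scheme is None:
            raise CompspectraError("codon_usage requires 'charsets' with frames")
        coding = PartitionScheme(
            {n: scheme.blocks[n] for n in scheme.frames},
            dict(scheme.frames),
            allow_overlap=True,
        )
        write_frame(codon_usage(aln, coding), "codon_usage.tsv")

    working: Alignment = aln
    mask_cfg = cfg.get("mask") or {}
    if mask_cfg:
        working, coord_map = mask_columns(
            working,
            scheme,
            drop_blocks=mask_cfg.get("drop_blocks", ()),
            drop_codon_pos=mask_cfg.get("drop_codon_pos", ()),
            drop_columns=mask_cfg.get("drop_columns", ()),
        )
        results["masked_length"] = working.length
    if cfg.get("recode") == "ry":
        working = recode_ry(working)

    if "rcfv" in analyses:
        profile = rcfv(working)
        write_frame(profile.to_frame(), "rcfv.tsv")
        results["rcfv_total"] = profile.total_rcfv
    if "rcv" in analyses:
        results["rcv"] = rcv(working)
        results["rcv_normalization"] = "n * mean counted sites per taxon"
    if "skew" in analyses:
        if working.alphabet.name == "dna":
            write_frame(skews(working), "skews.tsv")
        else:
            results["skew_skipped"] = f"alphabet {working.alphabet.name!r}"
    if "class_deviations" in analyses:
        if working.alphabet.name == "ry":
            write_frame(class_deviations(working, "R_Y"), "class_deviations_R_Y.tsv")
        else:
            for sch in ("AT_GC", "R_Y"):
                write_frame(
                    class_deviations(working, sch), f"class_deviations_{sch}.tsv"
                )
    if "spectrum" in analyses:
        sp_cfg = cfg.get("spectrum") or {}
        sp = spectrum(
            working,
            min_side=int(sp_cfg.get("min_side", 2)),
            groups=groups if sp_cfg.get("use_groups", True) else None,
            exclusive=bool(sp_cfg.get("exclusive", False)),
        )
        if groups is not None and groups.focal:
            sp = filter_focal(sp, groups)
        write_frame(spectrum_frame(sp).set_index("split"), "spectrum.tsv")
        payload = [
            {
                "split": list(s.split.key),
                "counts": s.counts,
                "columns": list(s.columns),
                "label": s.label,
            }
            for s in sp
        ]
        (out / "spectrum.json").write_text(json.dumps(payload, indent=1))
        outputs["spectrum.json"] = _sha256(out / "spectrum.json")
        if groups is not None and groups.hypotheses:
            write_frame(label_hypotheses(sp, groups), "hypotheses.tsv")

    manifest = {
        "tool": "compspectra",
        "version": __version__,
        "seed": cfg.get("seed", 0),
        "config": cfg,
        "inputs": inputs,
        "outputs": outputs,
        "results": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
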