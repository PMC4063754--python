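"""Shared fixtures: small simulated studies built at test time."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from polyase.formats import TranscriptRecord
from polyase.pipeline import RunConfig, run_end_to_end
from polyase.simulate import (
    build_strain_reference,
    generate_fragments,
    placements_to_pileup,
    simulate_experiment,
)

STRAINS = ("HNI", "OR", "SOK")


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """A 12-transcript simulated study with fixed allele fractions."""
    out = tmp_path_factory.mktemp("toy_sim")
    paths = simulate_experiment(
        out,
        seed=7,
        n_transcripts=12,
        transcript_length=1200,
        strains=STRAINS,
        dsnps_per_strain=5,
        parental_fragments=300,
        triploid_fragments=(600, 900),
        allele_fractions=(0.2, 0.3, 0.5),
    )
    return paths


@pytest.fixture(scope="session")
def toy_run(toy_dataset, tmp_path_factory):
    """The full pipeline executed on the toy study."""
    out_dir = tmp_path_factory.mktemp("toy_run")
    config = RunConfig(
        reference=toy_dataset["reference"],
        strains={s: toy_dataset[f"parent_{s}"] for s in STRAINS},
        triploids={"trpA": toy_dataset["triploid"]},
        out_dir=out_dir,
    )
    return run_end_to_end(config)


def build_custom_study(
    out_dir: Path,
    transcripts: dict[str, str],
    variants: dict[str, list[tuple[str, int, str]]],
    triploid_counts: dict[str, dict[str, int]],
    parental_fragments: int = 300,
    seed: int = 11,
):
    """Construct a study from explicit sequences, variants and read counts.

    ``variants`` maps strain -> [(transcript, position, base)];
    ``triploid_counts`` maps transcript -> strain -> fragment count.
    Returns the same path dict shape as ``simulate_experiment``.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    reference = [TranscriptRecord(tid, seq) for tid, seq in transcripts.items()]
    strains = list(variants)
    strain_seqs = {}
    for strain in strains:
        per_transcript = {}
        for rec in reference:
            subs = [
                (pos, base)
                for tid, pos, base in variants[strain]
                if tid == rec.id
            ]
            per_transcript[rec.id] = build_strain_reference(rec, subs).sequence
        strain_seqs[strain] = per_transcript

    from polyase.formats import write_fasta

    paths = {"reference": out_dir / "reference.fasta"}
    write_fasta(reference, paths["reference"])
    for strain in strains:
        placements = []
        for rec in reference:
            strain_rec = TranscriptRecord(rec.id, strain_seqs[strain][rec.id])
            placements.extend(
                generate_fragments(strain_rec, parental_fragments, strain, rng)
            )
        path = out_dir / f"parent_{strain}.mpileup"
        placements_to_pileup(placements, reference, strain_seqs, path)
        paths[f"parent_{strain}"] = path
    triploid = []
    for rec in reference:
        for strain in strains:
            n = triploid_counts.get(rec.id, {}).get(strain, 0)
            strain_rec = TranscriptRecord(rec.id, strain_seqs[strain][rec.id])
            triploid.extend(generate_fragments(strain_rec, n, strain, rng))
    paths["triploid"] = out_dir / "triploid.mpileup"
    placements_to_pileup(triploid, reference, strain_seqs, paths["triploid"])
    return paths
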