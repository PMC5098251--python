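"""File formats: parent reference, clone pools, landscapes, titrations.

Formats are deliberately plain: FASTA for sequences (clone multiplicity
as ``count=N`` in the description), TSV for the numbering map, titration
data and frequency tables, Newick for trees, YAML for landscape and
campaign configuration, JSON for reports and the reproducibility
manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import TitrationCurve
from .library import AffinityLandscape, MutagenesisConfig, Pool
from .selection import CampaignPlan, RoundConfig
from .sequence import ParentReference, VariantRecord


# -- parent reference --------------------------------------------------------


def write_parent(
    parent: ParentReference, fasta_path, map_path
) -> None:
    records = [
        SeqRecord(Seq(parent.vh_sequence), id="VH", description=""),
        SeqRecord(Seq(parent.vl_sequence), id="VL", description=""),
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {"chain": chain, "index": i, "label": lab,
         "region": parent.region_of(chain, lab)}
        for chain, i, lab, _ in parent.positions()
    ]
    pd.DataFrame(rows).to_csv(map_path, sep="\t", index=False)


def read_parent(fasta_path, map_path) -> ParentReference:
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    if set(seqs) != {"VH", "VL"}:
        raise ValueError(
            f"parent FASTA must contain exactly records 'VH' and 'VL', "
            f"found {sorted(seqs)}"
        )
    table = pd.read_csv(map_path, sep="\t", dtype={"label": str})
    labels = {"VH": {}, "VL": {}}
    regions = {}
    for row in table.itertuples():
        labels[row.chain][int(row.index)] = str(row.label)
        regions[(row.chain, str(row.label))] = row.region
    vh_labels = tuple(labels["VH"][i] for i in range(len(seqs["VH"])))
    vl_labels = tuple(labels["VL"][i] for i in range(len(seqs["VL"])))
    return ParentReference(seqs["VH"], seqs["VL"], vh_labels, vl_labels, regions)


# -- clone pools -------------------------------------------------------------


def write_pool_fasta(records: list[VariantRecord], path) -> None:
    """One FASTA record per clone; VH and VL concatenated; multiplicity
    encoded as ``count=N`` in the description."""
    out = [
        SeqRecord(
            Seq(r.vh_sequence + r.vl_sequence),
            id=r.id,
            description=f"count={r.count}",
        )
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def read_pool_fasta(path, parent: ParentReference) -> list[VariantRecord]:
    vh_len = len(parent.vh_sequence)
    total = vh_len + len(parent.vl_sequence)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if len(seq) != total:
            from .sequence import IndelNotSupportedError

            raise IndelNotSupportedError(
                f"record {rec.id}: length {len(seq)} differs from parent "
                f"scFv length {total}; indels are not supported"
            )
        count = 1
        for token in rec.description.split():
            if token.startswith("count="):
                count = int(token.split("=", 1)[1])
        records.append(
            VariantRecord.from_sequences(
                parent, seq[:vh_len], seq[vh_len:], rec.id, count
            )
        )
    return records


def pool_to_fasta(pool: Pool, parent: ParentReference, path) -> None:
    write_pool_fasta(pool.to_records(parent), path)


# -- landscape ---------------------------------------------------------------


def write_landscape(landscape: AffinityLandscape, path) -> None:
    doc = {
        "parent_kd": landscape.parent_kd,
        "effects": [
            {"mutation": k, "fold": float(v)}
            for k, v in sorted(landscape.effects.items())
        ],
        "clade1": sorted(landscape.clade1),
        "clade2": sorted(landscape.clade2),
        "epistasis_penalty": landscape.epistasis_penalty,
        "background": {
            "neutral": landscape.background_neutral,
            "deleterious": landscape.background_deleterious,
            "deleterious_range": list(landscape.deleterious_range),
            "beneficial_range": list(landscape.beneficial_range),
            "seed": landscape.background_seed,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_landscape(path) -> AffinityLandscape:
    doc = yaml.safe_load(Path(path).read_text())
    bg = doc.get("background", {})
    return AffinityLandscape(
        parent_kd=doc["parent_kd"],
        effects={e["mutation"]: e["fold"] for e in doc.get("effects", [])},
        clade1=frozenset(doc.get("clade1", [])),
        clade2=frozenset(doc.get("clade2", [])),
        epistasis_penalty=doc.get("epistasis_penalty", 10.0),
        background_neutral=bg.get("neutral", 0.80),
        background_deleterious=bg.get("deleterious", 0.15),
        deleterious_range=tuple(bg.get("deleterious_range", (1.0, 5.0))),
        beneficial_range=tuple(bg.get("beneficial_range", (0.8, 1.0))),
        background_seed=bg.get("seed", 0),
    )


# -- campaign configuration --------------------------------------------------


def read_campaign_plan(path) -> CampaignPlan:
    doc = yaml.safe_load(Path(path).read_text())
    rounds = [
        RoundConfig(
            n_beads=r.get("n_beads", 150_000),
            gate_mode=r.get("gate_mode", "library_top"),
            gate_fraction=r["gate_fraction"],
            antigen_conc=r.get("antigen_conc", 1.0),
        )
        for r in doc["rounds"]
    ]
    if not rounds:
        raise ValueError("campaign config lists no rounds")
    return CampaignPlan(
        rounds=rounds,
        mutagenesis=MutagenesisConfig(
            mean_mutations=doc.get("mean_mutations", 1.7)
        ),
        library_size=doc.get("library_size", 150_000),
        rerandomize_after=tuple(doc.get("rerandomize_after", (2,))),
    )


# -- titrations --------------------------------------------------------------


def read_titration_tsv(path) -> TitrationCurve:
    concs, responses = [], []
    lines = Path(path).read_text().splitlines()
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if ln == 1 and not _is_number(fields[0]):
            continue  # header
        try:
            concs.append(float(fields[0]))
            responses.append(float(fields[1]))
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed TSV at line {ln}") from exc
    return TitrationCurve(concs, responses)


def write_titration_tsv(curve: TitrationCurve, path) -> None:
    pd.DataFrame(
        {"concentration_nM": curve.concentrations, "mfs": curve.responses}
    ).to_csv(path, sep="\t", index=False)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# -- manifest ----------------------------------------------------------------


def write_manifest(outdir, config: dict, master_seed: int | None) -> None:
    """Record the configuration hash and seed for reproducibility."""
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "master_seed": master_seed,
    }
    Path(outdir, "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
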