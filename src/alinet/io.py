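"""Reading and writing: model files, statistic tables, cohorts, XDSL export.

File dialects
-------------
* Model-definition / model-structure files are YAML (JSON is a YAML subset
  and parses with the same loader).
* Statistic tables (published ratios, prevalences) are delimited text; the
  delimiter is sniffed from the extension (.csv / .tsv).
* Cohorts are delimited text (one column per variable, one row per
  individual) with a JSON sidecar recording the seed and the parameter-file
  hash.
* A compiled network can be exported to XDSL, the GeNIe network format, for
  cross-checking in that GUI; import is out of scope.
"""

from __future__ import annotations

import hashlib
import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .cpt import (
    EvidenceRecord,
    ModelSpec,
    PrevalenceRecord,
    QuartileRiskRecord,
)
from .network import ConditionalTable, Network, NetworkError, Variable

QUARTILE_MEASURE = "RRQ"


def _sep(path: Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def parse_evidence(text: str) -> dict[str, str]:
    """Parse ``"var=state,var2=state2"`` into an evidence mapping."""
    out: dict[str, str] = {}
    if not text.strip():
        return out
    for chunk in text.split(","):
        if "=" not in chunk:
            raise NetworkError(
                f"malformed evidence {chunk!r}; expected var=state[,var=state...]"
            )
        k, v = chunk.split("=", 1)
        out[k.strip()] = v.strip()
    return out


# -- statistic tables ------------------------------------------------------


def load_evidence_table(path: str | Path) -> tuple[list[EvidenceRecord], list[QuartileRiskRecord]]:
    """Read a published-statistics table (one row per reported ratio).

    Columns: exposure, exposure_state, outcome, adverse_state, measure,
    value, cutoff, source.  Rows with measure ``RRQ`` are per-quartile risk
    ratios and are grouped (in file order, one row per quartile) into
    :class:`QuartileRiskRecord` objects; RR / OR rows map one-to-one onto
    :class:`EvidenceRecord`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    required = {"exposure", "exposure_state", "outcome", "adverse_state", "measure", "value"}
    if missing := required - set(df.columns):
        raise NetworkError(f"{path}: missing column(s) {sorted(missing)}")
    records: list[EvidenceRecord] = []
    quartile_rows: dict[tuple[str, str, str], list[tuple[str, float, str, str]]] = {}
    for _, row in df.iterrows():
        measure = row["measure"].strip().upper()
        value = float(row["value"])
        cutoff = row.get("cutoff", "")
        source = row.get("source", "")
        if measure == QUARTILE_MEASURE:
            key = (row["exposure"], row["outcome"], row["adverse_state"])
            quartile_rows.setdefault(key, []).append(
                (row["exposure_state"], value, cutoff, source)
            )
        else:
            records.append(
                EvidenceRecord(
                    exposure=row["exposure"],
                    exposure_state=row["exposure_state"],
                    outcome=row["outcome"],
                    adverse_state=row["adverse_state"],
                    measure=measure,
                    value=value,
                    cutoff=cutoff,
                    source=source,
                )
            )
    quartiles: list[QuartileRiskRecord] = []
    for (exposure, outcome, adverse_state), rows in quartile_rows.items():
        if len(rows) != 4:
            raise NetworkError(
                f"{path}: quartile block {exposure} -> {outcome} has "
                f"{len(rows)} rows; need exactly 4"
            )
        quartiles.append(
            QuartileRiskRecord(
                exposure=exposure,
                outcome=outcome,
                adverse_state=adverse_state,
                values=tuple(v for _, v, _, _ in rows),
                cutoffs=tuple(c for _, _, c, _ in rows),
                source=rows[0][3],
            )
        )
    return records, quartiles


def load_prevalences(path: str | Path) -> list[PrevalenceRecord]:
    """Read a prevalence parameter file (variable, state, probability, provenance, source)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    if missing := {"variable", "state", "probability"} - set(df.columns):
        raise NetworkError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        PrevalenceRecord(
            variable=row["variable"],
            state=row["state"],
            probability=float(row["probability"]),
            provenance=row.get("provenance", "default-assumption") or "default-assumption",
            source=row.get("source", ""),
        )
        for _, row in df.iterrows()
    ]


def load_model_spec(
    model_path: str | Path,
    evidence_path: str | Path,
    prevalence_path: str | Path,
) -> ModelSpec:
    """Assemble a :class:`ModelSpec` from the three model files."""
    doc = yaml.safe_load(Path(model_path).read_text())
    variables = [
        Variable(str(v["name"]), tuple(str(s) for s in v["states"]))
        for v in doc.get("variables", [])
    ]
    gates = {
        str(child): (str(g["variable"]), str(g["state"]), str(g["forces"]))
        for child, g in (doc.get("gates") or {}).items()
    }
    aggregations = {
        str(child): [(str(p), str(s)) for p, s in pairs]
        for child, pairs in (doc.get("aggregation") or {}).items()
    }
    records, quartiles = load_evidence_table(evidence_path)
    prevalences = load_prevalences(prevalence_path)
    return ModelSpec(
        variables=variables,
        evidence_records=records,
        quartile_records=quartiles,
        prevalences=prevalences,
        aggregations=aggregations,
        gates=gates,
    )


# -- explicit network files ------------------------------------------------


def load_network(path: str | Path) -> Network:
    """Read an explicitly tabulated network (YAML or JSON).

    Schema::

        variables:
          - {name: exposure, states: [reference, exposed]}
          - {name: disease, states: ["no", "yes"]}
        tables:
          exposure:
            rows: [[0.7, 0.3]]
          disease:
            parents: [exposure]
            rows:                  # one row per parent configuration,
              - [0.9, 0.1]         # row-major in the declared parent order
              - [0.5, 0.5]

    ``rows`` may instead be a mapping from a comma-joined parent
    configuration (e.g. ``"exposed"`` or ``"exposed,Q1"``) to a row.  Rows
    within 1e-6 of summing to 1 are renormalised; worse rows are rejected.
    """
    doc = yaml.safe_load(Path(path).read_text())
    variables = {
        str(v["name"]): Variable(str(v["name"]), tuple(str(s) for s in v["states"]))
        for v in doc.get("variables", [])
    }
    tables = []
    for child_name, tdoc in (doc.get("tables") or {}).items():
        if child_name not in variables:
            raise NetworkError(f"{path}: table for unknown variable {child_name!r}")
        child = variables[child_name]
        parent_names = [str(p) for p in tdoc.get("parents", [])]
        for p in parent_names:
            if p not in variables:
                raise NetworkError(f"{path}: table for {child_name!r} references unknown parent {p!r}")
        parents = [variables[p] for p in parent_names]
        rows = tdoc["rows"]
        if isinstance(rows, Mapping):
            values = {tuple(str(k).split(",")) if k else (): v for k, v in rows.items()}
            if parents == []:
                ((_, row),) = values.items()
                values = row
        else:
            import numpy as np

            arr = np.asarray(rows, dtype=float)
            shape = tuple(p.card for p in parents) + (child.card,)
            values = arr.reshape(shape)
        tables.append(ConditionalTable(child, parents, values))
    return Network(variables.values(), tables)


# -- XDSL export -----------------------------------------------------------


def export_xdsl(net: Network, path: str | Path, network_id: str = "alinet") -> None:
    """Write the network in XDSL (the GeNIe XML format).

    Probabilities are listed per parent configuration in row-major order
    over the declared parent list (first parent slowest), child states
    fastest — the order GeNIe expects.
    """
    smile = ET.Element("smile", version="1.0", id=network_id, numsamples="10000")
    nodes = ET.SubElement(smile, "nodes")
    for name in net.topological_order():
        t = net.tables[name]
        cpt = ET.SubElement(nodes, "cpt", id=name)
        for s in net.variables[name].states:
            ET.SubElement(cpt, "state", id=_xdsl_id(s))
        if t.parents:
            ET.SubElement(cpt, "parents").text = " ".join(p.name for p in t.parents)
        ET.SubElement(cpt, "probabilities").text = " ".join(
            format(x, ".12g") for x in t.values.reshape(-1)
        )
    ext = ET.SubElement(smile, "extensions")
    genie = ET.SubElement(
        ext, "genie", version="1.0", app="alinet", name=network_id
    )
    for i, name in enumerate(net.topological_order()):
        node = ET.SubElement(genie, "node", id=name)
        ET.SubElement(node, "name").text = name
        ET.SubElement(node, "position").text = f"{40 + 120 * (i % 4)} {40 + 90 * (i // 4)} " \
                                               f"{140 + 120 * (i % 4)} {90 + 90 * (i // 4)}"
    tree = ET.ElementTree(smile)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def _xdsl_id(label: str) -> str:
    # XDSL state ids must be identifiers
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in label)
    return out if out and not out[0].isdigit() else f"s_{out}"


# -- cohort files ----------------------------------------------------------


def write_cohort(df: pd.DataFrame, path: str | Path, *, seed: int,
                 params_hash: str = "", extra: dict | None = None) -> None:
    """Write a cohort table plus its JSON sidecar (``<path>.meta.json``)."""
    path = Path(path)
    df.to_csv(path, sep=_sep(path), index=False)
    meta = {"seed": seed, "n": int(len(df)), "params_sha256": params_hash}
    meta.update(extra or {})
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return df, meta
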