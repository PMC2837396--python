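"""SWC reading and writing for bouton-annotated axon reconstructions.

Two dialects are supported:

``swc_typed`` (native)
    Standard 7-column SWC where the type code encodes the landmark kind:
    ``1`` soma / axon origin, ``2`` axon routing point, ``5`` bifurcation,
    ``7`` bouton, ``8`` white-matter segment.  Branch tips are type-2 leaf
    rows (inferred on read), so the files stay readable by generic SWC
    tools.

``swc_plus_annotations``
    Vanilla SWC (types 1/2, or any standard code treated as routing) plus a
    JSON sidecar ``<file>.ann`` listing bouton node ids and white-matter
    node ids, for interoperability with reconstructions that lack custom
    type codes::

        {"boutons": [12, 17, ...], "white_matter": [903, ...]}

Header comment lines of the form ``# key: value`` round-trip through
``metadata`` (values as strings); ``cell_class`` is promoted to the
reconstruction field.
"""

from __future__ import annotations

import json
from pathlib import Path

from .core import ArborReconstruction, MorphologyError, ParseError, ReconNode

_KIND_TO_CODE = {
    "origin": 1,
    "soma": 1,
    "routing": 2,
    "tip": 2,
    "bifurcation": 5,
    "bouton": 7,
    "white_matter": 8,
}
_CODE_TO_KIND = {1: "soma", 2: "routing", 5: "bifurcation", 7: "bouton",
                 8: "white_matter"}

DIALECTS = ("swc_typed", "swc_plus_annotations")


def _parse_rows(path: Path):
    metadata: dict[str, str] = {}
    rows = []  # (lineno, id, code, x, y, z, radius, parent)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    metadata[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                code = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            rows.append((lineno, nid, code, x, y, z, radius, parent))
    if not rows:
        raise ParseError(f"{path}: no sample rows found")
    return metadata, rows


def read_morphology(path, dialect: str = "swc_typed") -> ArborReconstruction:
    """Read an SWC file into a validated :class:`ArborReconstruction`.

    Raises :class:`ParseError` (naming the offending line) for malformed
    rows or orphan parent references and :class:`MorphologyError` for
    structural problems (cycles, missing origin).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    metadata, rows = _parse_rows(path)

    annotations: dict[str, set[int]] = {"boutons": set(), "white_matter": set()}
    if dialect == "swc_plus_annotations":
        sidecar = path.with_suffix(path.suffix + ".ann")
        if not sidecar.exists():
            raise ParseError(f"annotation sidecar {sidecar} not found")
        ann = json.loads(sidecar.read_text())
        annotations["boutons"] = set(ann.get("boutons", []))
        annotations["white_matter"] = set(ann.get("white_matter", []))

    ids = {nid for (_, nid, *_rest) in rows}
    n_children: dict[int, int] = {nid: 0 for nid in ids}
    for lineno, nid, code, x, y, z, radius, parent in rows:
        if parent != -1:
            if parent not in ids:
                raise ParseError(
                    f"{path}:{lineno}: node {nid} references "
                    f"parent id {parent} absent from file"
                )
            n_children[parent] += 1

    nodes = []
    for lineno, nid, code, x, y, z, radius, parent in rows:
        if dialect == "swc_typed":
            if code not in _CODE_TO_KIND:
                raise ParseError(
                    f"{path}:{lineno}: unsupported type code {code} "
                    f"(dialect swc_typed uses 1,2,5,7,8)"
                )
            kind = _CODE_TO_KIND[code]
        else:
            kind = "soma" if code == 1 else "routing"
            if nid in annotations["boutons"]:
                kind = "bouton"
            elif nid in annotations["white_matter"]:
                kind = "white_matter"
        if parent == -1:
            kind = "origin"
        elif kind == "soma":
            pass
        elif kind == "routing":
            if n_children[nid] == 0:
                kind = "tip"
            elif n_children[nid] >= 2:
                kind = "bifurcation"
        nodes.append(
            ReconNode(nid, kind, (x, y, z), radius,
                      None if parent == -1 else parent)
        )

    cell_class = metadata.pop("cell_class", "unspecified")
    recon = ArborReconstruction(nodes, cell_class=cell_class,
                                metadata=metadata)
    try:
        recon.validate()
    except ParseError:
        raise
    except MorphologyError as exc:
        raise MorphologyError(f"{path}: {exc}") from None
    return recon


def write_morphology(recon: ArborReconstruction, path) -> None:
    """Write the ``swc_typed`` dialect; lossless for every node field."""
    path = Path(path)
    lines = ["# arborcost SWC (swc_typed dialect)"]
    if recon.cell_class != "unspecified":
        lines.append(f"# cell_class: {recon.cell_class}")
    for key, val in recon.metadata.items():
        lines.append(f"# {key}: {val}")
    for n in sorted(recon.nodes, key=lambda n: n.id):
        code = _KIND_TO_CODE[n.kind]
        x, y, z = (float(v) for v in n.position)
        parent = -1 if n.parent_id is None else n.parent_id
        # repr() gives the shortest decimal that round-trips the double
        lines.append(
            f"{n.id} {code} {x!r} {y!r} {z!r} {float(n.radius)!r} {parent}"
        )
    path.write_text("\n".join(lines) + "\n")
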