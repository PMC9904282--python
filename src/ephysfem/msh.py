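"""MSH ASCII v2.2 mesh exchange (Gmsh legacy dialect).

Supports element types 4 (4-node tetrahedron) and 5 (8-node hexahedron).
The first element tag carries the tissue id.  Node coordinates are mm
in-file and converted to/from meters on I/O.
"""

from __future__ import annotations

import numpy as np

from .mesh import DEFAULT_TISSUES, FEMesh, MeshError, TissueTable, fix_tetra_orientation

_TYPE_TO_KIND = {4: ("tetra4", 4), 5: ("hexa8", 8)}
_KIND_TO_TYPE = {"tetra4": 4, "hexa8": 5}


def write_msh(mesh: FEMesh, path) -> None:
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write(f"$Nodes\n{mesh.n_vertices}\n")
        for i, (x, y, z) in enumerate(mesh.vertices * 1000.0, start=1):
            f.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
        f.write("$EndNodes\n")
        etype = _KIND_TO_TYPE[mesh.element_kind]
        f.write(f"$Elements\n{mesh.n_elements}\n")
        for i, (nodes, lab) in enumerate(zip(mesh.elements, mesh.labels), start=1):
            ns = " ".join(str(n + 1) for n in nodes)
            f.write(f"{i} {etype} 2 {lab} {lab} {ns}\n")
        f.write("$EndElements\n")


def read_msh(path, tissue_table: TissueTable = DEFAULT_TISSUES) -> FEMesh:
    with open(path) as f:
        lines = f.read().split("\n")
    i = 0

    def seek(tag):
        nonlocal i
        while i < len(lines) and lines[i].strip() != tag:
            i += 1
        if i >= len(lines):
            raise MeshError(f"MSH section {tag} not found")
        i += 1

    seek("$MeshFormat")
    version = lines[i].split()[0]
    if not version.startswith("2."):
        raise MeshError(f"unsupported MSH version {version}")
    seek("$Nodes")
    n = int(lines[i]); i += 1
    ids = np.empty(n, dtype=np.int64)
    xyz = np.empty((n, 3))
    for row in range(n):
        parts = lines[i + row].split()
        ids[row] = int(parts[0])
        xyz[row] = [float(parts[1]), float(parts[2]), float(parts[3])]
    i += n
    id_map = {int(v): k for k, v in enumerate(ids)}

    seek("$Elements")
    m = int(lines[i]); i += 1
    elements, labels, kind = [], [], None
    for row in range(m):
        parts = lines[i + row].split()
        etype = int(parts[1])
        if etype not in _TYPE_TO_KIND:
            continue  # skip surface/line elements
        k, nn = _TYPE_TO_KIND[etype]
        if kind is None:
            kind = k
        elif kind != k:
            raise MeshError("mixed tetra/hexa MSH files are not supported")
        ntags = int(parts[2])
        labels.append(int(parts[3]) if ntags >= 1 else 0)
        elements.append([id_map[int(p)] for p in parts[3 + ntags:3 + ntags + nn]])
    if kind is None:
        raise MeshError("no volume elements in MSH file")
    el = np.asarray(elements, dtype=np.int64)
    verts = xyz / 1000.0
    if kind == "tetra4":
        el = fix_tetra_orientation(el, verts)
    return FEMesh(
        vertices=verts,
        elements=el,
        element_kind=kind,
        labels=np.asarray(labels, dtype=np.int64),
        tissue_table=tissue_table,
    )
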