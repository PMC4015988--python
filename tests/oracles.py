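"""Independent brute-force oracles used by unit and acceptance tests.

These are deliberately naive (python loops, direct-sum formulas) and share
no code with the implementation they check.
"""

import numpy as np


def brute_force_rg(frame, mask):
    """Direct-sum mass-weighted radius of gyration."""
    m = frame.topology.masses[mask]
    xyz = frame.coords[mask]
    com = np.zeros(3)
    for mi, xi in zip(m, xyz):
        com += mi * xi
    com /= m.sum()
    acc = 0.0
    for mi, xi in zip(m, xyz):
        acc += mi * float(((xi - com) ** 2).sum())
    return float(np.sqrt(acc / m.sum()))


def brute_force_hbonds(frame, config):
    """All-pairs donor x acceptor scan under the geometric criterion."""
    top = frame.topology
    found = set()
    for d in range(top.n_atoms):
        if not top.is_donor[d]:
            continue
        for a in range(top.n_atoms):
            if not top.is_acceptor[a] or a == d:
                continue
            if (top.peptide_ids[d] == top.peptide_ids[a]
                    and top.residue_index[d] == top.residue_index[a]):
                continue
            dist = float(np.linalg.norm(frame.coords[d] - frame.coords[a]))
            if dist > config.hbond_distance:
                continue
            v1 = frame.coords[top.antecedent[d]] - frame.coords[d]
            v2 = frame.coords[a] - frame.coords[d]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= config.hbond_angle:
                found.add((d, a))
    return found
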