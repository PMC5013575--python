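# cliquescreen

Ligand-based virtual screening by maximum-common-substructure search.

Given one known active ligand (the *reference*) and a library of candidate
molecules in Tripos MOL2 format, `cliquescreen` ranks every library compound
by its structural similarity to the reference. It is aimed at the early,
desk-bound stage of drug discovery — shrinking a large vendor library to a
shortlist worth inspecting or purchasing — and at scaffold hopping: finding
actives whose core framework differs from the reference's. Output files
(ranked text list plus aligned mol2 files with a matched-pair comment
section) follow the conventions consumed by the LiSiCA PyMOL plugin, so runs
can be browsed in a structure viewer.

## Method

For each reference/target pair the common substructure is found as a
**maximum clique of a product graph**:

* a product-graph **vertex** is a pair of atoms (one per molecule) with
  identical SYBYL type (`C.ar` never matches `C.3`);
* an **edge** joins two vertices (i, i′) and (j, j′) when i ≠ j, i′ ≠ j′ and
  the internal relations agree —
  * **2D (topological)**: |d(i,j) − d(i′,j′)| ≤ s, where d counts covalent
    bonds along the shortest path and s is the *maximum allowed shortest
    path difference* (default 1 bond);
  * **3D (geometric)**: |‖xᵢ−xⱼ‖ − ‖xᵢ′−xⱼ′‖| ≤ t, with t the *maximum
    allowed spatial distance difference* in Å (default 1.0 Å).

A clique of this graph is an injective, internally consistent atom-to-atom
mapping; the maximum clique (found exactly by a deterministic
branch-and-bound with a greedy-colouring bound) is the maximum common
substructure. Each hit is scored with the graph-matching **Tanimoto
coefficient**

    Tc = c / (n_ref + n_tgt − c)

where c is the clique size and n_ref, n_tgt the molecules' kept-atom counts
(hydrogens are excluded by default). Compounds are ranked by decreasing Tc.
Records sharing a molecule name are treated as conformers of one compound;
in 3D the compound's score is its best conformer's. For 3D hits the target
is superposed onto the reference over the matched atoms (Kabsch
least-squares fit) and the matched-atom RMSD is reported in the aligned
output.

## Worked example

Screen benzene against a six-record library containing benzene itself,
toluene, and four synthetic molecules:

```sh
python - <<'EOF'
from dataclasses import replace
from pathlib import Path
from cliquescreen import FixtureSpec, benzene, toluene, make_library, write_mol2
lib = [benzene(), toluene()] + make_library(FixtureSpec(seed=4, n_heavy=(5, 9)), 4)
lib = [replace(m, record_index=i) for i, m in enumerate(lib)]
Path("reference.mol2").write_text(write_mol2([benzene()]))
Path("library.mol2").write_text(write_mol2(lib))
EOF
cliquescreen -R reference.mol2 -T library.mol2 -d 2 --spd 0 --top-k 5 --out-dir run
cat run/lisica_results.txt
```

prints

```
BENZENE	1.0000
TOLUENE	0.8571
MOL00002	0.1818
MOL00003	0.1538
MOL00001	0.0769
```

Benzene matches itself completely (c = n_ref = n_tgt = 6, Tc = 1). Toluene
shares the six aromatic ring carbons with benzene but carries one extra
heavy atom (the methyl carbon), so c = 6 of 6 + 7 atoms and
Tc = 6/(6+7−6) = 6/7 ≈ 0.8571. The synthetic molecules share only
incidental atom pairs and score low. Each `run/<rank>_<name>.mol2` holds
the reference and the (3D: superposed) target plus one comment line per
matched pair, e.g. `# pair 1 C.ar 1 C.ar`; `cliquescreen.load_run("run")`
reconstructs the full report from the directory.

The same screen from Python:

```python
from cliquescreen import ScreenConfig, benzene, toluene, build_graph, score_pair
r = score_pair(build_graph(benzene()), build_graph(toluene()),
               ScreenConfig(dimension=2, threshold_2d=0))
print(r.c, r.tanimoto)   # 6 0.8571428571428571
```

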