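# Methods

## Problem and model

`cliquescreen` implements similarity-based (ligand-based) virtual screening:
rank a library of small molecules by structural similarity to one reference
ligand, on the assumption that similar structures have similar activity.
Similarity is defined through the maximum common substructure (MCS) of the
two molecules, computed exactly as a maximum clique of a product graph.

Each molecule is first reduced to a `MolecularGraph`: the kept atoms (see
hydrogen policy below), their covalent-bond adjacency, the all-pairs
shortest-path matrix in bond counts (breadth-first search via
`scipy.sparse.csgraph.shortest_path`), and the Euclidean distance matrix of
the record's coordinates. The product graph of a reference graph R and
target graph T has one vertex per atom pair (i ∈ R, i′ ∈ T) with *identical
SYBYL type string*, and an edge between vertices (i, i′) and (j, j′) iff
i ≠ j, i′ ≠ j′ (the mapping must be injective) and the pair relation is
consistent:

* **2D rule** — both topological distances are finite and
  |d_R(i,j) − d_T(i′,j′)| ≤ s bonds;
* **3D rule** — |g_R(i,j) − g_T(i′,j′)| ≤ t Å.

Cliques of this graph are exactly the internally consistent atom-to-atom
mappings, so the maximum clique size c is the MCS size under the chosen
rule. The score is the graph-matching Tanimoto coefficient
Tc = c/(n_R + n_T − c) ∈ [0, 1], which is 1 iff the mapping covers both
molecules entirely and 0 iff no atom pair is type-compatible.

## Parameters

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| `dimension` | 2D topological vs 3D geometric rule | – | 2 | 2D needs no conformers and is conformation-independent |
| `threshold_2d` (`--spd`) | max shortest-path difference | bonds | 1 | smallest tolerance that forgives one-bond path distortions; 0 demands exact topological congruence |
| `threshold_3d` (`--tol`) | max spatial distance difference | Å | 1.0 | of the order of a bond-length change; 0 demands exact internal geometry |
| `top_k` | compounds reported | – | 100 | a shortlist of ~100 is what is typically inspected visually |
| `conformers_per_molecule` | conformers retained per compound (3D) | – | 1 | conformers are consumed, never generated |
| `include_h` | include hydrogens in the graphs | – | false | hydrogens roughly double graph sizes while adding little discrimination |
| `workers` | parallel processes | – | all cores | output is worker-count independent by construction |

Raising either threshold only ever adds product-graph edges, so clique size
and Tanimoto are non-decreasing in the threshold (a tested invariant).

## Numerical and algorithmic choices

* **Clique solver.** Exact branch-and-bound in the Tomita/MaxCliqueDyn
  family: vertices pre-ordered by descending degree (ties by index), each
  search node greedily colours its candidate set and prunes branches whose
  colour bound cannot beat the incumbent. Adjacency rows are Python-int
  bitsets. The search order is fully deterministic; among equal-size maximum
  cliques the first optimum in that fixed order is returned, so the same
  input always yields the same member set — the property all determinism
  guarantees rest on. A plain Bron–Kerbosch enumerator (guarded to 24
  vertices, no pivoting, no bounding) serves as an independent oracle in
  tests and in the acceptance script; `networkx.max_weight_clique` is a
  third route in the unit tests.
* **Disconnected molecules.** Topological distance across fragments is ∞,
  and any 2D comparison involving ∞ fails — including ∞ vs ∞ — so no
  topological consistency is ever asserted across fragments. The matched
  substructure itself is *not* required to be connected; an unconstrained
  clique may map a disconnected common substructure. Whether the mapping
  should be connectivity-constrained is a genuine design fork; the
  unconstrained variant is the strict product-graph semantics and is the
  one implemented.
* **Superposition.** Kabsch: SVD of the centred cross-covariance of the
  matched pairs, with the smallest singular direction flipped if the raw
  optimum is a reflection; RMSD is the root-mean-square residual over the
  matched pairs after the fit. With fewer than 3 pairs the rotation is
  underdetermined and the fit degrades to translation-only (identity
  rotation, centroid match) — a documented degenerate mode. The whole
  target molecule is transformed, not only the matched atoms, since a
  viewer needs the full aligned structure. RMSD is reported post-fit.
* **Tie-breaking.** Equal Tanimoto scores are ranked by ascending record
  index (file order); conformers within a compound by descending score,
  then record index. All file outputs are therefore byte-identical across
  repeated runs and worker counts.
* **Hydrogen/dummy policy.** An atom is a hydrogen iff the element part of
  its SYBYL type (text before the first `.`) is `H`, which covers `H`,
  `H.spc`, `H.t3p`. `Du`/`LP` atoms are parsed but always excluded from
  graphs. A record left atomless by the policy is skipped with a warning
  and counted in the report, not fatal.
* **MOL2 dialect.** Only `MOLECULE`, `ATOM`, `BOND` sections are
  interpreted; optional atom columns (substructure id/name, charge) are
  dropped on read and written with neutral defaults. Serials are preserved
  verbatim. Coordinates are written with 4 decimals; the generator rounds
  its coordinates to the same precision so read∘write round trips are exact
  identities. Comment lines in aligned outputs use `# key: value` for run
  metadata and `# pair <ref_serial> <ref_type> <tgt_serial> <tgt_type>` for
  matched pairs — the format `load_run` parses; no canonical syntax exists
  for this comment section, so this is this package's own convention.

## Synthetic data

`cliquescreen.fixtures` generates the molecules all tests and the
acceptance script run on. It emulates the *structural* properties screening
depends on — connected topologies (chains, random trees, rings, decorated
rings) over a SYBYL type alphabet, bond-length-scaled coordinates
(1.54 Å) with Gaussian jitter (default σ = 0.05 Å), multi-conformer
libraries as re-posed copies — and deliberately none of the chemistry:
no valence rules, no aromatic geometry optimisation, no energy
minimisation. Generation is a pure function of the `FixtureSpec`, which is
what makes byte-level determinism checks meaningful.

`make_known_mcs_pair` plants a provable truth: both molecules contain an
identical chain core (same types, same topology, rigidly transformed same
geometry), and each side's decoration atoms use SYBYL types absent from the
partner molecule and from the core, attached only as pendants. Decorations
therefore contribute no product-graph vertices and cannot shorten any
core-core path, so at 2D threshold 0 the planted core is exactly the
maximum clique — recovery is guaranteed by construction, not
probabilistically.

Consequently, passing tests demonstrate the algorithmic contracts
(exactness, invariances, determinism, round trips) but say nothing about
chemical enrichment on real actives/decoys, which would require external
databases and is outside this package's scope.

## Problem sizes

The verification computations use sizes at which the exhaustive oracle is
feasible and the whole suite stays quick: random graphs up to 18 vertices
at densities 0.3/0.5/0.7 (600 instances), planted pairs with cores of 2–6
atoms in molecules of up to 10 heavy atoms (100 pairs), screening libraries
of 25 molecules, and a 1000-molecule round-trip corpus. The solver itself
has no such limits; product graphs of drug-sized molecules (tens of heavy
atoms) solve in milliseconds to seconds depending on type diversity.

## Known limitations

* Exact SYBYL-type equality is the strictest compatibility rule; software
  that collapses subtypes (e.g. all carbons) would match more atoms.
* No conformer generation: 3D screening quality depends entirely on the
  conformers supplied in the library file.
* The maximum-clique problem is NP-hard; pathological product graphs
  (large molecules with a single atom type) can be slow, and no heuristic
  fallback is provided — exactness is the contract.
* Scores rank a library but carry no statistical calibration (no p-values,
  no enrichment estimate).
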