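# ensmap

Ensemble fragment-based hot-spot mapping for the discovery of
non-orthosteric (putative allosteric) binding sites on receptor
structures.

Allosteric pockets are often *cryptic*: they form transiently in the
conformational dynamics of a receptor and are invisible in any single
experimental structure.  `ensmap` implements the ensemble strategy for
finding them: take many conformers of the receptor, reduce them to a
small set of representatives, dock a library of small organic probe
fragments exhaustively over each representative's surface, aggregate
the low-energy probe clusters into ranked **consensus sites** (CSs) —
hot spots where several probe types congregate — and finally rank
individual residues by their probe contacts across the whole ensemble,
splitting them into orthosteric and non-orthosteric sets and grouping
the non-orthosteric ones into candidate allosteric sites.

The pipeline stages (each usable on its own):

1. **Reduction** — Kabsch superposition, all-pairs RMSD, GROMOS-style
   (Daura) neighbor clustering at 1.5 Å; the top 15 cluster centers
   become the representative ensemble.
2. **Mapping** — 16 rigid probe fragments (ethanol … benzene …
   N,N-dimethylformamide) are scored at every orientation × grid
   translation on precomputed LJ + Coulomb energy grids; the 2000 best
   poses per probe are rigid-body minimized and clustered, the 6
   lowest-mean-energy clusters per probe kept, and clusters of all
   probes aggregated into CSs ranked by how many probe clusters they
   incorporate (top 10 reported).
3. **Profiling** — probe–protein heavy-atom contacts within 5 Å are
   counted per residue, summed over all representatives, expressed as
   percentages of all contacts, ranked; the top 40 residues are
   classified orthosteric/non-orthosteric by ligand proximity and the
   non-orthosteric ones grouped into candidate sites together with the
   probes they bind.

Because real receptor MD ensembles are far beyond desk scale, the
package ships a first-class synthetic generator: a pseudo-receptor
helix bundle with a constitutive orthosteric notch (holding a reference
ligand) and a planted **cryptic pocket** that opens only in a subset of
conformers, with ground-truth labels for both.  Every downstream stage
is tested against these ground truths.  See `docs/methods.md` for the
models, parameters and limitations.

## Worked example

```python
from ensmap import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=7), "run_out")

print("clusters:", [(c.size, c.center_model) for c in report.reduction.clusters])
print("occupancy: %.1f%%" % report.reduction.occupancy_of_top_k)
for site in report.sites[:3]:
    print("site %d: %d residues, %.1f%% of contacts" %
          (site.site_id, len(site.residues), site.summed_percentage))
```

With the default synthetic study conditions (30 conformers, 40% of them
with the pocket open, seed 7) this prints:

```
clusters: [(18, 0), (12, 3)]
occupancy: 100.0%
site 1: 11 residues, 32.0% of contacts
site 2: 10 residues, 22.3% of contacts
```

Reduction finds exactly the two planted conformational states (18
closed conformers centered on model 0, 12 open ones centered on model
3) and the retained representatives cover 100% of the ensemble.  Site 2
is the recovered cryptic pocket: its residues (`A9–A18`, `B14`) are the
planted pocket lining, and mapping the open representative places a
top-3 consensus site within ~2 Å of the planted pocket center.  Site 1
is a surface canyon near the orthosteric notch.  The run directory
contains the residue table (`residue_table.tsv` — rank, residue, raw
contact count, percentage, orthosteric flag, site id), the per-site
summary, per-representative mapped structures with their probe poses as
HETATM records, and run metadata.

The same stages are available from the shell:

```bash
ensmap synth --out data --seed 7
ensmap reduce --ensemble data/ensemble.pdb --out reduced
ensmap map --structure structure.pdb --out-prefix mapped/run1
ensmap profile --mapping-results mapped/run1_mapped.pdb --ligand data/ligand.pdb --out profile
ensmap run --out full_run --seed 7
```

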