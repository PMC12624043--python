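# cryptosite

Most post-translational modifications decorate residues on a protein's
surface, where modifying enzymes can reach them. A sizeable fraction of
experimentally observed *phosphosites*, however, sit on serines, threonines
and tyrosines that are completely buried in the native fold — residues a
kinase could only reach while the protein is still folding. `cryptosite`
implements the computational pipeline for mining such **cryptic
phosphosites** from structure and PTM data, together with the supporting
analyses:

- **Accessibility** — Shrake-Rupley SASA, RSA normalization against
  extended Gly-X-Gly maximum areas, and the cryptic classification
  (RSA ≤ 0.15 in regions with AlphaFold confidence pLDDT ≥ 65).
- **Dynamical filtering** — prune low-confidence segments, merge contacting
  segments (≥ 5 residue pairs within 5 Å), drop entries under 40 residues,
  recompute RSA, decompose each entry into quasi-rigid domains with a
  β-Gaussian elastic network + spectral clustering of distance
  fluctuations, and keep only sites whose side chains make ≥ 80 %
  intra-domain contacts (Pidc ≥ 0.80).
- **Conservation** — the normalized column entropy
  S = −Σ p_α ln p_α / ln K (K = 22: amino acids + gap + ambiguity), with
  BUSCO-style IQR proteome filtering and Cohen's d effect sizes.
- **Mutation cross-referencing** — COSMIC/PTMVar-style screen tables,
  deduplication with counts, phosphomimetic calls (S/T/Y → D/E).
- **Folding bias** — ratchet-and-pawl dynamics on a contact-map progress
  variable Q with the bias-functional score
  T = Σ (mγ)⁻¹ ∫ |F^B|² dτ, exercised by a coarse-grained Gō-chain toy
  that tracks the solvent exposure of a buried bead along trajectories.
- **Synthetic data** — seeded lattice fixtures (globules, hinges, PTM/MSA/
  mutation tables, toy chains) with exact planted truth for every stage.

The real inputs of a proteome-scale run (PhosphoSitePlus, the AlphaFold
human proteome, reference proteomes, COSMIC) are bulk downloads; the
package consumes their file dialects but ships generators that emulate
each of them, so everything is testable at desk scale.

## Worked example

Generate a fixture battery and run the full pipeline:

```sh
cryptosite fixtures --seed 1 --out demo/fixtures
cryptosite refine --pdb-dir demo/fixtures --ptm demo/fixtures/ptm.tsv --out demo/refine
```

prints the stage waterfall:

```json
{
  "input": 19,
  "after_scan_cryptic": 7,
  "confident": 12,
  "excluded:exposed_after_pruning": 1,
  "cryptic": 5,
  "excluded:boundary": 1,
  "final_cryptic": 5
}
```

Of 19 PTM rows, 12 sites are solvent exposed (`confident`, i.e.
non-cryptic — including the decoy ubiquitination/acetylation rows planted
at surface lysines), 7 look buried in the static structures, and the
dynamical filter then removes one site that had been buried only by a
low-confidence loop (`exposed_after_pruning`) and one that sits at a
quasi-rigid domain interface (`excluded:boundary`). The 5 survivors are
exactly the deep-core sites the generators planted. `demo/refine/sites.tsv`
carries per-site SASA, RSA, pLDDT, Pidc and full provenance
(e.g. `raw>mapped>cryptic>cryptic`); `domains.tsv` lists per-residue domain
labels with the chosen subdivision and its quality.

A biased folding run of the 30-bead toy:

```sh
cryptosite foldtoy --seed 1 --out demo/foldtoy
# Q_final/Q_nat = 0.537, T = 1.534
```

reports the final contact-map progress relative to the native state and the
accumulated bias score T (T = 0 for unbiased runs, `--bias-k 0`); the
trajectory table contains Q and the core bead's solvent exposure per frame.

Library use mirrors the CLI:

```python
from cryptosite import pipeline, structio, synthetic_data

structure, truth = synthetic_data.make_globule_fixture(seed=1, low_conf_loop=True)
sites = structio.read_ptm_table(
    synthetic_data.make_ptm_fixture([(structure, truth)], seed=1))
result = pipeline.run_full({truth.accession: structure}, sites)
print(result.waterfall)
```

## Layout

```
src/cryptosite/
  structio.py        # PDB (AlphaFold dialect), PTM TSV, aligned FASTA
  accessibility.py   # Shrake-Rupley SASA, RSA, cryptic classification
  dynamic_filter.py  # prune/merge/gate, ENM modes, quasi-rigid domains, Pidc
  conservation.py    # entropic score, IQR filter, effect sizes
  mutation_xref.py   # screen preprocessing, phosphomimetic cross-referencing
  folding_bias.py    # ratchet-and-pawl bias, bias functional, Go-chain toy
  synthetic_data.py  # seeded fixture generators with planted truth
  pipeline.py, cli.py
docs/methods.md      # models, parameters, numerical choices, limitations
```
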