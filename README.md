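# lcaroot

Diagnosing and mitigating **long-branch attraction (LBA)** in small
phylogenomic datasets — for molecular systematists working on deep splits
where every available outgroup is highly divergent and one ingroup lineage
evolves much faster than the rest.

In that situation the fast branch is often drawn toward the outgroup, so
rooting on the outgroup places the fast lineage spuriously at the base of
the ingroup. `lcaroot` implements a four-part protocol to detect and avoid
this:

* **supermatrix editing** — concatenate per-gene alignments; remove
  *singleton* positions (columns where at least one sequence carries a
  character state found in exactly one sequence); delete taxa, e.g. one of
  two near-identical strain sequences, so that states shared only by the
  strain pair become detectable singletons;
* **exhaustive ML tree search** — for n ≤ 8 taxa, score all (2n−5)!!
  unrooted topologies under LG/GTR/JC with +Γ, +I and +F extensions
  (Felsenstein pruning with per-edge eigen-space branch optimization),
  nonparametric bootstrap supports;
* **LCA rooting** — reconstruct the marginal maximum-likelihood ancestral
  sequence of the ingroup on a **star** intree (so no ingroup hypothesis is
  presumed), replace the outgroup with this reconstructed last common
  ancestor, and root on its branch;
* **a sequence-evolution simulator** with a canned LBA scenario (one fast
  lineage represented by a two-strain cherry, one distant outgroup) so the
  whole pipeline is testable end to end without any downloads.

The core statistic is the standard pruning log-likelihood
`ln L = Σ_sites ln Σ_c w_c π' P(t₁r_c) ⋯ P(t_k r_c) δ_site` under a
reversible model `Q = S·diag(π)` (unit expected rate), with discrete-Γ
categories `r_c` and an invariant rate-0 category; the LCA sequence is the
per-site MAP state of the posterior `p(s) ∝ π_s Π_tips P(s→x_tip; t_tip r_c)`
mixed over categories. See `docs/methods.md` for the full model description
and design choices.

## Worked example

Simulate one replicate of the LBA scenario (a deep rapid radiation: internal
edges 0.01, ordinary pendants 0.1, fast lineage 1.0, outgroup 2.0
substitutions/site, L = 5000, LG+Γ generator) and run the four-analysis
protocol with an equal-rates LG+F inference model:

```python
from lcaroot import LBAScenarioSpec, make_lba_scenario
from lcaroot.ancestor import run_lba_protocol
from lcaroot.simulate import fast_lineage_is_basal

scenario = make_lba_scenario(LBAScenarioSpec(seed=1))
report = run_lba_protocol(
    scenario.alignment, scenario.outgroup,
    strain_pair=scenario.strain_tips, model="LG+F",
)
for a in report.analyses.values():
    print(f"{a.name} {a.dataset:<16} L={a.alignment_length:<5} "
          f"lnL={a.log_likelihood:>10.1f}  {a.tree.to_newick(lengths=False)}")
```

prints

```
A full+outgroup    L=5000  lnL=  -42968.4  (outgroup,((basal,(middle,sister)),(fast_A,fast_B)));
B noSing-ingroup   L=1938  lnL=   -8870.7  (((basal,middle),sister),fast_A,fast_B);
C noSing-kept-fast_A L=1303  lnL=   -4003.3  (basal,(fast_A,sister),middle);
C noSing-kept-fast_B L=1303  lnL=   -4008.9  (basal,(fast_B,sister),middle);
D ingroup+LCA      L=5000  lnL=  -31598.0  (LCA,((basal,middle),((fast_A,fast_B),sister)));
```

Reading the output: in analysis **A** the fast strain pair clusters with the
outgroup — rooting there would make it the basalmost ingroup lineage, and
indeed `fast_lineage_is_basal` on the outgroup-rooted ingroup tree returns
`True`. The edited datasets tell the opposite, artifact-free story: after
singleton pruning and strain deletion (**C**, 1303 of 5000 columns left) the
fast lineage clusters with its true sister regardless of which strain is
kept, and the LCA-rooted tree (**D**) recovers the generating rooted
topology, `fast_lineage_is_basal(...)` → `False`. The alignment lengths
decrease A ≥ B ≥ C because editing only removes columns, while D reuses the
full-length ingroup alignment with the reconstructed ancestor in place of
the outgroup.

The same steps are available from the shell:

```bash
lcaroot simulate --seed 1 --out-prefix rep1
lcaroot protocol --aln rep1.fasta --outgroup outgroup \
    --strains fast_A,fast_B --model LG+F --out rep1.report.json
lcaroot asr-root --aln rep1.fasta --outgroup outgroup --model LG+F \
    --lca-fasta rep1.lca.fasta
```

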