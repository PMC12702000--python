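# allonet

Dual-modality mapping of mutation-driven allosteric networks in proteins.

Point mutations far from an enzyme's active site can reshape its
conformational ensemble along "allosteric tendrils" — chains of residues
whose structure or dynamics respond to the distal perturbation. `allonet`
maps such networks by combining two complementary experiments on a
mutant/wild-type pair and then asking whether the combined network
overlaps externally defined residue sets (e.g. coevolving sectors) more
than chance:

1. **Room-temperature crystallography — weighted isomorphous difference
   density (IADDAT).** Given two merged amplitude sets on the same crystal
   form, the pipeline scales F_mut onto F_WT, forms difference structure
   factors ΔF = F_mut − F_WT with error-adaptive weights

   w = [1 + σ²(ΔF)/⟨σ²(ΔF)⟩ + α·ΔF²/⟨ΔF²⟩]⁻¹,  α = 0.05,

   phases them from the reference model, Fourier-synthesises the
   difference map Δρ, and integrates |Δρ| over voxels above a noise
   threshold (default 0.04 e⁻/Å³) lying within 1.5 Å of a protein heavy
   atom, averaged per residue (IADDAT: integration of absolute difference
   density above threshold).

2. **Local HDX-MS — residue-level differential deuterium uptake.** From
   peptide centroid-mass tables (states × timepoints × replicates, with
   undeuterated and fully-deuterated controls), the pipeline computes
   back-exchange-corrected percent deuteration
   %D = 100·(m_t − m₀)/(m_FD − m₀) per peptide, mutant−WT differences
   Δ%D, and projects them to single residues by inverse-amide-count
   weighted averaging over each peptide's exchange-reporting amides.

3. **Combined network and overlap statistics.** Residues with normalized
   IADDAT > 0.13 and/or |Δ%D| > 7 points at 300 s are pooled into the
   combined network X, which is compared against a residue sector Y
   within the measurable population N by the Jaccard ratio
   J(X,Y) = |X∩Y|/|X∪Y| and the one-sided hypergeometric tail
   p = P(K ≥ |X∩Y|).

A fully synthetic generator (toy P1 crystal, mutation-like atomic edits,
noisy amplitudes, pepsin-like peptide maps with planted exchange
differences) provides ground-truthed inputs so that every stage is
testable without any external data.

## Worked example

Generate a synthetic study (40-residue chain, side-chain deletion +
ordered water at residue 25, 0.5 Å side-chain shifts of the tendril
{10, 12, 30}, 5 % amplitude noise, planted Δ%D segments, 1.5-point HDX
noise) and run the full analysis:

```python
from allonet import benchmark_scenario
from allonet.pipeline import (analyze_pair, combine_network,
                              compare_sectors, measurable_population)
from allonet.network import jaccard
from allonet.synthetic import planted_sector, random_sector

sc = benchmark_scenario(seed=7)
pair = analyze_pair("mut", sc.wt_model, sc.wt_reflections,
                    sc.mut_reflections, sc.hdx_table)
network = combine_network([pair])
population = measurable_population(sc.wt_model, sc.hdx_table)

print("IADDAT set :", sorted(k.resnum for k in pair.iaddat_set.members))
print("network    :", sorted(k.resnum for k in network.members))
print("Jaccard(planted, network) = %.3f" % jaccard(sc.truth.perturbed, network))
for res in compare_sectors(network, [planted_sector(sc.truth, 40, seed=7),
                                     random_sector(21, 40, seed=7)], population):
    print(f"{res.y_label}: |X∩Y|={res.n_intersection}, "
          f"J={res.jaccard:.3f}, p={res.p_hypergeometric:.2e}")
```

Output:

```
IADDAT set : [10, 12, 25, 30]
network    : [8, 9, 10, 11, 12, 13, 22, 23, 24, 25, 26, 28, 29, 30, 31, 32, 33]
Jaccard(planted, network) = 0.789
planted-sector: |X∩Y|=15, J=0.652, p=1.09e-04
random-sector: |X∩Y|=11, J=0.407, p=1.57e-01
```

The difference map pinpoints the four crystallographically perturbed
residues exactly; the HDX track adds the planted exchange segments
around them; the pooled network overlaps a sector containing the planted
tendril far beyond chance (p ≈ 10⁻⁴) while a random sector of the same
size does not (p ≈ 0.16).

The same pipeline runs from the shell on files:

```sh
allonet simulate --n-res 40 --site 25 --tendril 10,12,30 --seed 7 -o sim/
allonet diffmap --wt-reflections sim/wt_reflections.csv \
                --mut-reflections sim/mut_reflections.csv \
                --wt-model sim/wt.pdb -o out/dm
allonet hdx --table sim/hdx.csv -o out/hdx
allonet network --iaddat out/dm/iaddat.csv --hdx out/hdx/residue_dhdx.csv \
                --sector sectorB.txt -o out/net
```

Real data enter the same way: MTZ or CSV reflection files, PDB/mmCIF
models, and a long-format peptide CSV
(`state,sequence,start,end,timepoint_s,replicate,centroid_mass_da`,
with `timepoint_s = 0` for undeuterated and `FD` for fully-deuterated
control rows).

## Limitations

The synthetic crystal is a single poly-Ala-like helix in P1 with uniform
B-factors and no solvent model, and uptake kinetics are a two-parameter
logistic — adequate for validating the analysis chain, not for emulating
any particular protein. See `docs/methods.md` for the model, parameter
and design details.
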