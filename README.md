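# thermopath

Thermodynamically constrained minimal-pathway enumeration in stoichiometric
metabolic networks.

## The problem

Central carbon metabolism hides latent routes: combinations of native
enzymes that could carry glycolytic flux but never do under ordinary
conditions. A classic case is the conversion of glycerol to pyruvate in
*E. coli*, which canonically runs through lower Embden–Meyerhof–Parnas (EMP)
glycolysis but can in principle also proceed through the Entner–Doudoroff
(ED) pathway, a methylglyoxal bypass, or a "serine shunt" (serine
biosynthesis followed by deamination). Searches that demand a positive ATP
yield miss the last two entirely — one is ATP-neutral, the other wastes ATP.

`thermopath` finds such routes systematically. Given a stoichiometric
network, per-reaction standard transformed Gibbs energies ΔrG′°, and
metabolite concentration ranges, it searches for the smallest sets of
reactions that balance a target net conversion while being simultaneously
thermodynamically favourable, and enumerates alternative solutions per ATP
yield. It is aimed at people designing or analysing synthetic metabolic
routes with constraint-based models.

## The method

A net-conversion "objective reaction" is injected into the network,

&nbsp;&nbsp;&nbsp;&nbsp;glycerol + *n* ADP + *n* Pi ⟶ pyruvate + *n* ATP,

where *n* is the required ATP yield, and its rate is fixed at
*v*<sub>obj</sub> = −1 so the rest of the network must supply the conversion
at unit rate. After splitting every reversible reaction into forward and
backward copies (all rates non-negative), the search is a mixed-integer
linear program over rates *v*, binary activity indicators *z* and
log-concentrations *x* = ln *c*:

```
minimise   Σᵢ zᵢ
subject to S v = 0,            v_obj = −1
           0 ≤ vᵢ ≤ β zᵢ       (β = 10)
           vᵢ ≥ ε zᵢ           (ε = 1e-3; active reactions carry flux)
           −g⁰ᵢ − (Sᵀx)ᵢ + Mᵢ(1 − zᵢ) ≥ 0     (second law, big-M)
           ln Cmin ≤ x ≤ ln Cmax               (default 1 μM – 10 mM)
           z_fwd + z_bwd ≤ 1
```

with g⁰ᵢ = ΔrG′°ᵢ/RT. One solve yields the shortest feasible pathway;
alternatives are enumerated by adding integer cuts that exclude all
indicator vectors within Hamming radius 2 of each found solution, stopping
after 10 solutions per ATP yield. Solutions are re-verified by plain
arithmetic, classified into strategies by their committing enzymes (Eno/Pyk,
Eda, MgsA, SdaA), and post-processed for exact net-ATP bookkeeping and
carbon-route segments.

The MILP runs on the HiGHS solver via `scipy.optimize.milp`; additional
backends can be registered. SBML (L3+FBC) and BiGG-style JSON models are
read through COBRApy; a curated 36-metabolite / 32-reaction central-carbon
network containing all four strategies ships with the package, along with
generators for random planted-pathway networks and a brute-force
enumeration oracle.

## Worked example

```
$ thermopath run --model fixture --atp-yields -1,0,1 --out out/
21 solutions, 4 strategies (ED, EMP, methylglyoxal, serine_shunt) -> out
```

At yield −1 the shortest route (6 reactions) is the methylglyoxal bypass via
the direct isomerase: GLPK, GLPD, MGSA, HCHA, DLD plus quinol oxidation —
it spends the glycerol-kinase ATP and never recovers it. At yield 0 the
serine shunt appears (13 reactions; net ATP exactly 0), and at yield +1 the
only solution is lower EMP glycolysis (10 reactions, net ATP +1). The
annotation table in `out/annotations.tsv` lists, per solution, the strategy
labels, the exact rational net ATP per pyruvate, and the lengths of the
methylglyoxal→pyruvate and 3PG→(serine)→pyruvate segments; across the scan
the methylglyoxal→pyruvate conversion is realised by exactly 3 distinct
segments and the serine segment always has 4 reactions (SerA, SerC, SerB,
SdaA). Restricting the scan to yields ≥ 1 (`--atp-yields 1,2`) loses both
cryptic strategies — the ATP-yield filter effect.

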