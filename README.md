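# caaxbind

Structure-based prediction of farnesyltransferase (FTase) substrate
specificity from C-terminal **Cxxx** tetrapeptide motifs.

Protein farnesylation attaches a 15-carbon isoprenoid to a cysteine in the
C-terminal Ca₁a₂X motif. Which tetrapeptides react is determined largely by
whether they can bind the FTase peptide groove, where three structural
features are strictly conserved: coordination of the Cys Sγ by the
catalytic-site triad (replacing the Zn²⁺ in the model), a hydrogen bond
from the C-terminal carboxylate to a glutamine of the α subunit, and one
from the a₂ backbone carbonyl to an arginine of the β subunit. `caaxbind`
exploits this: it **threads** a query Cxxx sequence onto a template peptide
backbone, **packs** its side chains from a rotamer library, **minimizes**
all peptide torsions, the peptide rigid body, receptor interface side
chains and ligand dihedrals under harmonic versions of the three conserved
contacts (DFP quasi-Newton, tolerance 10⁻⁴), and **scores** the result.

The classification score is the *peptide score without reference energies*,

    E_pep = Σ_{i∈{C,a1,a2,X}} E_i − E_ref(aa_i),

where `E_i` is residue *i*'s share of the pairwise energy
(Lennard-Jones + hydrogen bonding + implicit solvation + electrostatics,
pair terms split half/half) and `E_ref` is a per-amino-acid constant
(zero by default). Lower is better; two thresholds (loose/stringent)
classify sequences as `binder` / `strong_binder` / `non_binder`. Because
the energy model is self-contained, thresholds should be calibrated on
labeled data (`caaxbind.calibrate_thresholds`) rather than transferred
from other force fields. Interface score, total score and buried interface
surface area (Shrake–Rupley) are also available.

Everything runs against a self-contained synthetic template — a miniature
pocket with the same anchor architecture — so no structure downloads are
needed; any real receptor–peptide complex in PDB format can be supplied
with an anchor configuration instead.

## Worked example

```python
import caaxbind as cb

template = cb.make_toy_template()          # deterministic synthetic pocket
for motif in ("CVIM", "CRKD"):             # KRas-2B motif vs charged control
    rec = cb.score_sequence(template, motif)
    print(f"{rec.sequence}  {rec.score:.2f}")
```

prints

```
CVIM  -8.24
CRKD  -3.94
```

i.e. the canonical aliphatic-a₂ motif CVIM threads into the toy pocket with
a strongly favorable peptide energy, while the charged-a₂/acidic-X control
pays steric and desolvation penalties. On this template, thresholds
calibrated from the synthetic benchmark put the binder cut near −5.9 energy
units: CVIM classifies as a binder and CRKD does not. The shipped −0.4/−1.1
defaults are interface conventions inherited from the classical protocol and
should always be replaced by `calibrate_thresholds` output for a given
template and parameter set (see `docs/methods.md`).

Scanning a proteome for candidate substrates:

```python
hits = cb.scan_proteome("proteins.fasta")            # C-terminal Cxxx motifs
records = cb.score_sequences(template, {h.motif.letters for h in hits})
```

The same operations are exposed on the command line:

```bash
caaxbind score --seq CVIM              # score one motif on the toy template
caaxbind batch --in seqs.txt           # TSV of scores + classifications
caaxbind enumerate                     # all 8000 Cxxx sequences
caaxbind scan --fasta proteome.fa      # C-terminal motif scan
caaxbind roc --in labeled.tsv          # AUC / operating points, lower=binder
caaxbind fixtures --out fx/ --seed 1   # emit synthetic template + labels
```

External templates: `caaxbind --config conf.toml score --template cplx.pdb
--seq CVLS`, where the TOML names the peptide chain, ligand codes and the
five anchor atoms (`[template.anchors]`, `chain:seqpos:atom`).

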