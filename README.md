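# lysogenkit

A curation toolkit for **prophages** — temperate phage genomes integrated
into bacterial chromosomes.  Automated predictors (PHASTER-style tools)
find candidate prophage regions but routinely miss the exact boundaries,
split one phage into several calls, or mistake transposase-dense islands
for phages.  `lysogenkit` implements the manual curation workflow that
fixes this, as a reusable, testable pipeline:

* **Boundary refinement via att sites.**  Site-specific integration leaves
  near-identical short direct repeats (attL/attR, 10–25 bp) at the two
  phage/host junctions.  The scanner aligns a window centred on each rough
  boundary against the other and enumerates every repeat pair with core
  length `L ∈ [10, 25]` and Hamming mismatches `m ≤ 2`, ranked by the score
  `s = L − 2m`.  attL sits next to the integrase, attR next to the lysin;
  a phage whose lysogeny module lies at the right repeat is reported as
  reverse-complement.
* **Integration-locus assignment.**  The att core is intersected with the
  annotation: integration into a tRNA/tmRNA gene or a conserved CDS (e.g.
  *lepA*) leaves a partial gene copy at one junction and the restored
  full-length gene at the other; otherwise the locus is non-coding.
* **Gene-module completeness.**  Genes are categorized by product keywords
  into the canonical temperate-phage modules (lysogeny → replication →
  packaging → head → tail → fiber → lysis).  A prophage is *intact* when
  all six essential modules are present and both att sites were found;
  exactly one defect makes it *questionable*; anything worse *incomplete*.
  Transposases, orphan methyltransferases and methyltransferase +
  endonuclease (restriction–modification candidate) contexts are flagged,
  and prophage fragments split across contigs can be re-joined.
* **Integrase phylogenetics.**  Marker genes (integrase, terminase large
  subunit) are compared with Needleman–Wunsch global alignment; distances
  use the Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)`; trees are
  built by Saitou–Nei neighbor joining with column-resampling bootstrap
  supports.  Integrases cluster into *insertion groups* that share a
  chromosomal integration locus; a phage whose integrase clusters with one
  group while integrating elsewhere is flagged as an outlier.
* **Phage–host codon usage.**  Per-amino-acid synonymous codon fractions
  for phage vs host CDS (host conventionally includes the prophage),
  prophage tRNA inventories excluding the partial integration-site copies,
  and anticodon decoding including the Ile2 lysidine rule
  (tRNA-Ile(CAU) reads the minor AUA codon after TilS modification).
* **Synthetic lysogens.**  A generator (`synth_forge`) emits complete
  lysogen genomes with known ground truth — planted att repeats, module
  layout, integration locus, codon bias — so every stage is testable
  without downloading data.

## Worked example

Forge a synthetic lysogen (a 50 kb host background with a ~41 kb phage
cassette integrated into a serine tRNA gene), hand the refiner a
deliberately sloppy candidate region, and read back the curated call:

```bash
$ lysogenkit forge --seed 11 --out forged
wrote synthetic_lysogen_11 to forged

# candidate 800 bp short on the left, 500 bp long on the right
$ echo -e "synthetic_lysogen_11_c1\t25273\t67679\tintact" > cand.bed
$ lysogenkit refine --fasta forged/*.fasta --gff forged/*.gff3 \
      --bed cand.bed --out refined.tsv
refined 1 candidate(s) -> refined.tsv
```

`refined.tsv` (report coordinates are 1-based inclusive):

```
genome                contig                   start  end    orientation  att_status  attL                 attR                 mismatches  locus     verdict
synthetic_lysogen_11  synthetic_lysogen_11_c1  26074  67181  forward      both        TCTAACGACTTATGGAAAC  TCTAACGACTTATGGAAAC  0           tRNA:Ser  intact
```

The true prophage spans 26074–67179: the scanner recovered the planted
repeat exactly (the reported 19 bp core is the planted 17 bp core plus two
coincidentally matching flanking bases), relabelled the locus as the
serine tRNA gene the phage disrupted, and upgraded the sloppy candidate to
an att-delimited *intact* call with all six gene modules present.

The same steps are available as library calls
(`forge_lysogen`, `find_att_pair`, `refine_prophage`, `profile_modules`,
`assess_completeness`, `nj_tree`, `bootstrap_support`, `assign_groups`,
`codon_usage` / `compare_phage_host`, `summarize_cohort`).

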