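9dce8bcdfb1cb820ac7fc8bfd50152f3cdf0575091b199d1ba8a7441f294bdea  annotations.tsv
dbf7695262a5ab2b56175d25cfb6b99fa8115fc56ef263a38872e205482a6fe2  config.yaml
97589a478d290a9e3ac1ae31ac7c0e5b1d8d89785cdbf13d19fda4fe33ef8299  conserved_cys.tsv
c8137d9bf192dee5cf54686d8b01cfdd62b1e4ec7ecec716e1340d2348c0a456  egf_alignment.synthetic.afa
8a7635a0a86582c114de38a5e0d9782cef0be8c2662d3f276ec033e4053c746b  family_precursors.synthetic.fasta
f5e85a5f650b68a9428e93ce30728a0ed8aea6963b08febcc47b0937113d861f  mutations.tsv
f1fc7205752a450eca51bf19f765ab4cc987b3e690ee268e50b9333d8f7bf6a0  partner_domains.tsv
8c3da5343ec4e7b49081509da1d78ee8b017e5fb603e823ce2e0ff69f154857d  partner_precursors.synthetic.fasta
4798f94df6c47e82c45ab4dd95449693ae51a47d23f2cc161f6699f73fae9f5a  prodomain_alignment.synthetic.afa
57e0dfe7544eda0d2c12781672f93e5df9ee73951ef89135d36965f4676abdb3  tb_docking_alignment.synthetic.afa
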