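total_samples,agreed_category,disagreed_category,agreed_subcategory,disagreed_subcategory
200,177,23,168,32
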