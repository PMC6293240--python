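site_name,forums,threads,posts,members
Breastcancer.org Community,80,121688,3608324,153620
Breast Cancer Care,54,36949,782486,NA
Susan G Komen Foundation: Message Board,24,44175,354592,26883
Triple Negative Breast Cancer: Forums,17,9641,100706,123427
No Surrender Breast Cancer Foundation,36,2443,55498,5549
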