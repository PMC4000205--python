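classification_method,classifier_class
tree-based methods,interaction
logistic regression,interaction
support vector machine,interaction
k-nearest neighbours,interaction
artificial neural network,interaction
weighted voting,interaction
discriminant analysis,non-interaction
prediction analysis of microarrays,non-interaction
compound covariate predictor,non-interaction
nearest centroid,non-interaction
LASSO,non-interaction
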