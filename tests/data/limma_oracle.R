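# Independent oracle: limma eBayes moderated t on the synthetic fixture
# produced by tests/conftest.py::limma_fixture_matrix (seed 20240917).
# Regenerate limma_moderated_t_expected.tsv with:
#   Rscript limma_oracle.R   (run next to a limma_fixture.tsv export)
suppressMessages(library(limma))
x <- as.matrix(read.delim("limma_fixture.tsv", row.names=1))
design <- cbind(Intercept=1, case=c(1,1,1,1,0,0,0,0))
fit <- eBayes(lmFit(x, design))
out <- data.frame(feature=rownames(x), t=fit$t[,"case"], p=fit$p.value[,"case"])
write.table(format(out, digits=15), "limma_moderated_t_expected.tsv",
            sep="\t", quote=FALSE, row.names=FALSE)
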